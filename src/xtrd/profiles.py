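"""Cross-marker descriptive summaries.

* the opposite sire-TRD decay profile across the pseudoautosomal region
  (per-marker male/female sire-TRD and an isotonic, non-increasing fit of
  |alpha| against distance from the pseudoautosomal boundary);
* LD (r^2) decay by region class;
* run reports counting significant results per TRD pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .trio_data import MISSING
from .regions import PSEUDOAUTOSOMAL, HETEROSOMAL
from .inference import TrdResult

#: log10 BF below which the opposite sex counts as "null TRD"
NULL_BF_LOG10 = 0.5


@dataclass
class DecayProfile:
    frame: pd.DataFrame  # pos, dist, alpha_s_m, alpha_s_f, abs_alpha, fitted
    boundary_bp: int


def trd_decay_profile(results: list[TrdResult], boundary_bp: int) -> DecayProfile:
    """Sire-TRD by distance to the pseudoautosomal boundary.

    Expects per-marker results with sex-specific sire parameters
    (``alpha_s_m``, ``alpha_s_f``).  The fit is an isotonic non-increasing
    regression of mean |alpha| on distance; the ``opposite`` column flags
    markers with decisive, opposite-signed TRD in the two sexes.
    """
    rows = []
    for r in results:
        if "alpha_s_m" not in r.params or "alpha_s_f" not in r.params:
            continue
        am = r.mean("alpha_s_m")
        af = r.mean("alpha_s_f")
        rows.append(
            {
                "id": r.id,
                "pos": r.start_bp,
                "dist": abs(r.start_bp - boundary_bp),
                "alpha_s_m": am,
                "alpha_s_f": af,
                "abs_alpha": (abs(am) + abs(af)) / 2,
                "opposite": (
                    np.sign(am) * np.sign(af) < 0
                    and r.log10_bf.get("alpha_s_m", -np.inf) >= 2
                    and r.log10_bf.get("alpha_s_f", -np.inf) >= 2
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values("dist").reset_index(drop=True) \
        if rows else pd.DataFrame(
            columns=["id", "pos", "dist", "alpha_s_m", "alpha_s_f",
                     "abs_alpha", "opposite", "fitted"]
        )
    if len(df):
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        df["fitted"] = iso.fit_transform(df["dist"], df["abs_alpha"])
    return DecayProfile(frame=df, boundary_bp=boundary_bp)


def ld_decay(
    genotypes,
    labels,
    bins=(0, 1e6, 5e6, 2e7, 1e8),
    max_pairs: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 per distance bin and region class.

    r^2 is the squared Pearson correlation of genotype codes (composite LD);
    monomorphic pairs are excluded.  ``genotypes`` is a GenotypeTable,
    ``labels`` the per-marker classifications (or label strings).
    """
    lab = np.array(
        [c.label if hasattr(c, "label") else c for c in labels], dtype=object
    )
    calls = genotypes.calls.astype(float)
    calls[calls == MISSING] = np.nan
    pos = genotypes.markers.pos
    rng = np.random.default_rng(seed)
    rows = []
    for region in (PSEUDOAUTOSOMAL, HETEROSOMAL):
        idx = np.nonzero(lab == region)[0]
        if len(idx) < 2:
            continue
        pairs = [(i, j) for k, i in enumerate(idx) for j in idx[k + 1:]]
        if len(pairs) > max_pairs:
            pick = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[p] for p in pick]
        for i, j in pairs:
            x, y = calls[i], calls[j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            rows.append((region, abs(pos[j] - pos[i]), r * r))
    df = pd.DataFrame(rows, columns=["region", "dist", "r2"])
    if df.empty:
        return pd.DataFrame(columns=["region", "bin", "mean_r2", "n_pairs"])
    df["bin"] = pd.cut(df["dist"], bins=list(bins), include_lowest=True)
    out = (
        df.groupby(["region", "bin"], observed=True)["r2"]
        .agg(mean_r2="mean", n_pairs="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# pattern taxonomy


PATTERNS = ("opposite-sire", "single-sex-sire", "dam", "recessive",
            "unspecific")


def classify_patterns(results: list[TrdResult]) -> dict:
    """Assign each significant result exactly one primary pattern label.

    Precedence: opposite-sex sire > single-sex sire > dam > recessive >
    unspecific.  "Opposite" needs decisive BF in both sexes with opposite
    signs; "single-sex" needs one decisive sex and log10 BF below
    ``NULL_BF_LOG10`` in the other.
    """
    assigned = {}
    for r in results:
        if not any(bf >= 2 for bf in r.log10_bf.values()):
            continue
        label = None
        am = r.params.get("alpha_s_m")
        af = r.params.get("alpha_s_f")
        if am is not None and af is not None:
            bm = r.log10_bf.get("alpha_s_m", -np.inf)
            bf_ = r.log10_bf.get("alpha_s_f", -np.inf)
            if bm >= 2 and bf_ >= 2 and np.sign(am[0]) * np.sign(af[0]) < 0:
                label = "opposite-sire"
            elif (bm >= 2 and bf_ < NULL_BF_LOG10) or \
                 (bf_ >= 2 and bm < NULL_BF_LOG10):
                label = "single-sex-sire"
        if label is None and any(
            p.startswith("alpha_d") and r.log10_bf.get(p, -np.inf) >= 2
            for p in r.params
        ):
            label = "dam"
        if label is None and r.log10_bf.get("alpha_g", -np.inf) >= 2:
            label = "recessive"
        if label is None:
            label = "unspecific"
        assigned[id(r)] = (r, label)
    counts = {p: 0 for p in PATTERNS}
    for _, lab in assigned.values():
        counts[lab] += 1
    return {"labels": [(r.id, lab) for r, lab in assigned.values()],
            "counts": counts,
            "n_significant": len(assigned)}


def report(results: list[TrdResult], out_dir, profile: DecayProfile | None = None,
           ld: pd.DataFrame | None = None, make_plots: bool = True) -> dict:
    """Write a run summary: pattern counts, result table, optional plots.

    Re-running over the same inputs rewrites identical content
    (idempotent).
    """
    from .trio_data import write_results

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = classify_patterns(results)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {"counts": summary["counts"],
             "n_significant": summary["n_significant"],
             "n_results": len(results)},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    write_results(results, out / "results.tsv")
    if profile is not None and len(profile.frame):
        profile.frame.to_csv(out / "decay_profile.tsv", sep="\t", index=False)
    if ld is not None and len(ld):
        ld.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
    if make_plots and profile is not None and len(profile.frame):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        f = profile.frame
        ax.scatter(f["dist"] / 1e6, f["alpha_s_m"], s=12, c="tab:blue",
                   label="male offspring")
        ax.scatter(f["dist"] / 1e6, f["alpha_s_f"], s=12, c="tab:red",
                   label="female offspring")
        ax.plot(f["dist"] / 1e6, f["fitted"], c="k", lw=1.5,
                label="isotonic |alpha|")
        ax.set_xlabel("distance from pseudoautosomal boundary (Mb)")
        ax.set_ylabel("sire-TRD (alpha)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "decay_profile.png", dpi=120)
        plt.close(fig)
    return summary
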