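"""Trio phasing, sliding-window haplotypes and windowed TRD scans.

Phasing is rule-based and conservative: hemizygous male calls phase
trivially, female offspring inherit the sire's hemizygous allele as
paternal, and heterozygous pseudoautosomal calls resolve only when a parent
is homozygous.  Unresolved sites are flagged and windows containing a
flagged site for an individual exclude that individual — no statistical
imputation is performed.

Sliding windows (sizes 2, 4, 10 and 20 markers, step 1) are recoded with the
biallelic-haplotype procedure: each distinct haplotype above a frequency
floor is tested in turn as pseudo-allele A against all other haplotypes
pooled as B, and each pseudo-marker is analyzed with the same transmission
and inference machinery as a single SNP.  Windows with fewer than 10
heterozygous dams or fewer than 50 informative offspring are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trio_data import MISSING, MALE, FEMALE, TrioSet
from .regions import HETEROSOMAL
from .transmissions import TransmissionCounts, MatingGenotypeTable, POOLED
from .inference import (
    TrdModelSpec, McmcConfig, TrdResult,
    fit_allelic, fit_genotypic, empirical_null,
)

logger = logging.getLogger(__name__)

#: allele codes in phased arrays
UNRESOLVED = -1
ABSENT = -2  # no paternal X at heterosomal markers of males


@dataclass
class PhasedTrioSet:
    """Per-trio ordered offspring alleles (paternal, maternal).

    ``pat``/``mat`` have shape (n_markers, n_trios) with values 0 (allele A),
    1 (allele B), ``UNRESOLVED`` or ``ABSENT``.  Male offspring at
    heterosomal markers carry exactly one (maternal) allele.
    """

    trioset: TrioSet
    pat: np.ndarray
    mat: np.ndarray
    labels: list = field(default_factory=list)

    @property
    def markers(self):
        return self.trioset.markers

    def resolved_maternal(self) -> np.ndarray:
        return self.mat >= 0


def _marker_labels(labels, n: int) -> list[str]:
    if labels is None:
        return [HETEROSOMAL] * n
    return [c.label if hasattr(c, "label") else c for c in labels]


def phase_trios(trioset: TrioSet, labels=None) -> PhasedTrioSet:
    """Resolve offspring allele phase from trio genotypes.

    ``labels`` gives the per-marker region label (defaults to heterosomal
    everywhere).  Sites violating the inheritance rules, or unresolvable
    without imputation, are flagged ``UNRESOLVED``.
    """
    n_markers = trioset.genotypes.n_markers
    n_trios = len(trioset)
    lab = _marker_labels(labels, n_markers)

    pat = np.full((n_markers, n_trios), UNRESOLVED, dtype=np.int8)
    mat = np.full((n_markers, n_trios), UNRESOLVED, dtype=np.int8)

    male = trioset.off_sex == MALE
    female = trioset.off_sex == FEMALE

    calls = trioset.genotypes.calls
    s = calls[:, trioset.sire_idx]
    d = calls[:, trioset.dam_idx]
    o = calls[:, trioset.off_idx]

    for m in range(n_markers):
        if lab[m] == HETEROSOMAL:
            # males: single maternal allele
            mm = male & (o[m] != MISSING) & (o[m] != 1)
            mat[m, mm] = (o[m, mm] // 2).astype(np.int8)
            pat[m, male] = ABSENT
            # females: paternal allele is the sire's hemizygous allele
            ff = female & (o[m] != MISSING) & ((s[m] == 0) | (s[m] == 2))
            p_allele = (s[m] // 2).astype(np.int8)
            m_allele = (o[m] - p_allele).astype(np.int8)
            ok = ff & ((m_allele == 0) | (m_allele == 1))
            pat[m, ok] = p_allele[ok]
            mat[m, ok] = m_allele[ok]
        else:
            known = (o[m] != MISSING)
            hom = known & (o[m] != 1)
            pat[m, hom] = (o[m, hom] // 2).astype(np.int8)
            mat[m, hom] = (o[m, hom] // 2).astype(np.int8)
            het = known & (o[m] == 1)
            sire_hom = het & ((s[m] == 0) | (s[m] == 2))
            pat[m, sire_hom] = (s[m, sire_hom] // 2).astype(np.int8)
            mat[m, sire_hom] = (1 - s[m, sire_hom] // 2).astype(np.int8)
            dam_hom = het & (s[m] == 1) & ((d[m] == 0) | (d[m] == 2))
            mat[m, dam_hom] = (d[m, dam_hom] // 2).astype(np.int8)
            pat[m, dam_hom] = (1 - d[m, dam_hom] // 2).astype(np.int8)

    return PhasedTrioSet(trioset=trioset, pat=pat, mat=mat, labels=lab)


@dataclass
class HaplotypeWindow:
    start: int  # first marker index
    size: int
    start_bp: int
    end_bp: int
    catalog: dict = field(default_factory=dict)  # haplotype -> frequency


@dataclass
class ConsolidatedRegion:
    representative: TrdResult
    members: list
    peak_log10_bf: float
    smoothed_score: float


def _window_dam_data(phased: PhasedTrioSet, start: int, size: int):
    """Maternal haplotype + dam complement per trio over one window.

    Returns (m_hap, c_hap, dam_ids, off_sex) restricted to trios with fully
    resolved maternal alleles and a compatible dam genotype.
    """
    ts = phased.trioset
    sl = slice(start, start + size)
    mat = phased.mat[sl]
    dam = ts.genotypes.calls[sl][:, ts.dam_idx]
    ok = np.all(mat >= 0, axis=0) & np.all(dam != MISSING, axis=0)
    comp = dam - mat
    ok &= np.all((comp >= 0) & (comp <= 1), axis=0)
    idx = np.nonzero(ok)[0]
    m_hap = [tuple(mat[:, i]) for i in idx]
    c_hap = [tuple(comp[:, i]) for i in idx]
    return m_hap, c_hap, ts.dam_id[idx], ts.off_sex[idx], idx


def _hap_label(h) -> str:
    return "".join("AB"[a] for a in h)


def window_catalog(phased: PhasedTrioSet, start: int, size: int) -> HaplotypeWindow:
    """Haplotype catalog (dam haplotype pool frequencies) of one window."""
    markers = phased.markers
    m_hap, c_hap, _, _, _ = _window_dam_data(phased, start, size)
    pool = m_hap + c_hap
    freqs: dict = {}
    for h in pool:
        freqs[h] = freqs.get(h, 0) + 1
    tot = max(len(pool), 1)
    return HaplotypeWindow(
        start=start,
        size=size,
        start_bp=int(markers.pos[start]),
        end_bp=int(markers.pos[start + size - 1]),
        catalog={_hap_label(h): k / tot for h, k in freqs.items()},
    )


def scan_windows(
    phased: PhasedTrioSet,
    sizes=(2, 4, 10, 20),
    spec: TrdModelSpec | None = None,
    config: McmcConfig | None = None,
    min_het_dams: int = 10,
    min_informative: int = 50,
    freq_floor: float = 0.005,
    null_reps: int = 100_000,
    null_seed: int = 0,
    region: str = HETEROSOMAL,
) -> list[TrdResult]:
    """Sliding-window dam-TRD scan with biallelic haplotype recoding.

    One result per (window, pseudo-allele).  Windows spanning a region-label
    boundary are skipped; windows failing the heterozygous-dam or
    informative-offspring floors are discarded.
    """
    spec = spec or TrdModelSpec(region=region, parents=("dam",))
    markers = phased.markers
    lab = phased.labels
    results: list[TrdResult] = []
    n_markers = len(markers)
    for size in sizes:
        for start in range(0, n_markers - size + 1):
            wl = set(lab[start:start + size])
            if wl != {region}:
                logger.debug("window %d+%d spans a label boundary; skipped",
                             start, size)
                continue
            m_hap, c_hap, dam_ids, off_sex, _ = _window_dam_data(
                phased, start, size
            )
            if not m_hap:
                continue
            pool = m_hap + c_hap
            freqs: dict = {}
            for h in pool:
                freqs[h] = freqs.get(h, 0) + 1
            tot = len(pool)
            catalog = {h: k / tot for h, k in freqs.items()}
            for h, f in sorted(catalog.items(), key=lambda kv: -kv[1]):
                if f < freq_floor:
                    continue
                is_m = np.array([x == h for x in m_hap])
                is_c = np.array([x == h for x in c_hap])
                het = is_m ^ is_c
                n_informative = int(het.sum())
                n_het_dams = len(set(dam_ids[het]))
                if n_het_dams < min_het_dams or n_informative < min_informative:
                    continue
                n_a = int((is_m & het).sum())
                n_b = n_informative - n_a
                counts = TransmissionCounts(
                    n_a_dam=n_a, n_b_dam=n_b,
                    n_het_dams=n_het_dams, n_informative=n_informative,
                    stratum=POOLED,
                )
                res = fit_allelic(
                    counts, spec=spec, config=config,
                    id=f"{markers.pos[start]}:{markers.pos[start + size - 1]}",
                    chrom=markers.chrom[start],
                    start_bp=int(markers.pos[start]),
                    end_bp=int(markers.pos[start + size - 1]),
                    window_size=size,
                    stratum=POOLED,
                )
                res.marker_index = start
                res.pseudo_allele = _hap_label(h)
                if n_informative > 0 and null_reps:
                    null = empirical_null(
                        n_informative, n_reps=null_reps, seed=null_seed,
                        bin_counts=True,
                    )
                    res.random_trd_class = null.classify(res.mean("alpha_d"))
                results.append(res)
    return results


def consolidate(
    results: list[TrdResult],
    bandwidth_markers: float | None = None,
    min_log10_bf: float = 2.0,
    max_class: str = "<=0.001%",
) -> list[ConsolidatedRegion]:
    """Group overlapping significant windows into regions.

    Per-window scores (max log10 BF over its pseudo-alleles) are smoothed
    along the marker index with a Gaussian kernel; significant windows
    (BF >= 100 and random-TRD class at or below ``max_class``) are grouped by
    marker-interval overlap and each group is represented by the member
    window with the maximal smoothed score.
    """
    if not results:
        return []
    from .inference import RANDOM_TRD_CLASSES, CLASS_NONE

    order = [c for c, _ in RANDOM_TRD_CLASSES] + [CLASS_NONE]
    max_rank = order.index(max_class)

    # collapse pseudo-alleles to one score per (window start, size)
    windows: dict = {}
    for r in results:
        key = (r.marker_index, r.window_size)
        best = windows.get(key)
        bf = max(r.log10_bf.values()) if r.log10_bf else -np.inf
        if best is None or bf > best[1]:
            windows[key] = (r, bf)
    keys = sorted(windows)
    centers = np.array([k[0] + (k[1] - 1) / 2 for k in keys])
    scores = np.array([windows[k][1] for k in keys])
    if bandwidth_markers is None:
        bandwidth_markers = float(np.median([k[1] for k in keys]))
    bw = max(bandwidth_markers, 1e-6)
    diff = (centers[:, None] - centers[None, :]) / bw
    kern = np.exp(-0.5 * diff ** 2)
    smoothed = kern @ scores / kern.sum(axis=1)

    sig = []
    for i, k in enumerate(keys):
        r, bf = windows[k]
        cls = r.random_trd_class
        rank = order.index(cls) if cls in order else len(order)
        if bf >= min_log10_bf and rank <= max_rank:
            sig.append((k[0], k[0] + k[1] - 1, i))
    if not sig:
        return []
    sig.sort()
    groups = [[sig[0]]]
    for item in sig[1:]:
        if item[0] <= groups[-1][-1][1] + 1:  # overlapping or adjacent
            groups[-1].append(item)
        else:
            groups.append([item])
    out = []
    for g in groups:
        members = [windows[keys[i]][0] for _, _, i in g]
        best = max(g, key=lambda item: smoothed[item[2]])
        rep = windows[keys[best[2]]][0]
        out.append(
            ConsolidatedRegion(
                representative=rep,
                members=members,
                peak_log10_bf=float(max(windows[keys[i]][1] for _, _, i in g)),
                smoothed_score=float(smoothed[best[2]]),
            )
        )
    return out


def recessive_scan(
    phased: PhasedTrioSet,
    sizes=(2, 4, 10, 20),
    config: McmcConfig | None = None,
    min_het_dams: int = 10,
    min_informative: int = 50,
    freq_floor: float = 0.005,
    region: str = HETEROSOMAL,
) -> list[TrdResult]:
    """Genotypic (recessive) TRD scan on female offspring, heterosomal region.

    For each window pseudo-allele, female offspring of heterozygous-carrier
    dams are tabulated by sire carrier class and offspring genotype, and the
    genotypic model is fitted.  Results report the observed and
    Mendelian-expected homozygote counts in carrier-sire matings.
    """
    ts = phased.trioset
    markers = phased.markers
    lab = phased.labels
    results: list[TrdResult] = []
    n_markers = len(markers)
    for size in sizes:
        for start in range(0, n_markers - size + 1):
            if set(lab[start:start + size]) != {region}:
                continue
            m_hap, c_hap, dam_ids, off_sex, idx = _window_dam_data(
                phased, start, size
            )
            if not m_hap:
                continue
            sl = slice(start, start + size)
            sire_calls = ts.genotypes.calls[sl][:, ts.sire_idx[idx]]
            sire_ok = np.all((sire_calls == 0) | (sire_calls == 2), axis=0)
            sire_hap = [tuple(sire_calls[:, i] // 2) for i in range(len(idx))]

            pool = m_hap + c_hap
            freqs: dict = {}
            for h in pool:
                freqs[h] = freqs.get(h, 0) + 1
            tot = len(pool)
            for h, k in sorted(freqs.items(), key=lambda kv: -kv[1]):
                if k / tot < freq_floor:
                    continue
                is_m = np.array([x == h for x in m_hap])
                is_c = np.array([x == h for x in c_hap])
                het_dam = is_m ^ is_c
                use = het_dam & (off_sex == FEMALE) & sire_ok
                if not np.any(use):
                    continue
                n_het_dams = len(set(dam_ids[use]))
                n_informative = int(use.sum())
                if n_het_dams < min_het_dams or n_informative < min_informative:
                    continue
                table = MatingGenotypeTable(stratum=FEMALE)
                for i in np.nonzero(use)[0]:
                    sire_is_h = sire_hap[i] == h
                    off_copies = int(sire_is_h) + int(is_m[i])
                    key = ("A", "AB") if sire_is_h else ("B", "AB")
                    # genotype index relative to pseudo-allele A = h
                    table.add(key, 2 - off_copies)
                res = fit_genotypic(
                    table, config=config,
                    id=f"{markers.pos[start]}:{markers.pos[start + size - 1]}",
                    chrom=markers.chrom[start],
                    start_bp=int(markers.pos[start]),
                    end_bp=int(markers.pos[start + size - 1]),
                    window_size=size,
                    stratum=FEMALE,
                    region=region,
                )
                res.marker_index = start
                res.pseudo_allele = _hap_label(h)
                carrier = table.classes.get(("A", "AB"))
                if carrier is not None:
                    observed_hom = int(carrier[0])
                    expected_hom = float(carrier.sum()) / 2.0
                    res.flags.append(
                        f"homozygotes observed={observed_hom} "
                        f"expected={expected_hom:.1f}"
                    )
                results.append(res)
    return results
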