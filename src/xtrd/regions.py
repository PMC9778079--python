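"""Pseudoautosomal vs heterosomal marker classification.

Each trio of genotype codes is checked for Mendelian consistency under two
inheritance models:

* **pseudoautosomal** — the standard autosomal rule: the offspring genotype
  must be composable from one sire allele and one dam allele;
* **heterosomal** — males are hemizygous: a male offspring carries a single
  maternal allele (array-coded 0 or 2; a heterozygous male call is itself
  inconsistent), a female offspring carries the sire's hemizygous allele plus
  one dam allele (a heterozygous sire call is inconsistent under this model).

Markers in the true heterosomal region show near-zero inconsistency under
the heterosomal rule and a materially positive rate under the
pseudoautosomal rule, and vice versa; this contrast labels each marker and
contiguous runs of labels segment the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trio_data import MISSING, MALE, FEMALE, TrioSet

PSEUDOAUTOSOMAL = "pseudoautosomal"
HETEROSOMAL = "heterosomal"
UNDETERMINED = "undetermined"
DISCORDANT = "discordant-removed"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNINFORMATIVE = "uninformative"

_MODELS = (PSEUDOAUTOSOMAL, HETEROSOMAL)

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _pseudo_ok(s: int, d: int, o: int) -> bool:
    sa, da, oa = set(_ALLELES[s]), set(_ALLELES[d]), _ALLELES[o]
    for x in sa:
        for y in da:
            if tuple(sorted((x, y))) == oa:
                return True
    return False


def _hetero_ok(s: int, d: int, o: int, sex: str) -> bool:
    da = set(_ALLELES[d])
    if sex == MALE:
        # single maternal allele, array-coded 0 or 2; sire is ignored
        if o == 1:
            return False
        return (o // 2) in da
    # female: sire hemizygous allele (sire 1 is itself inconsistent) + dam allele
    if s == 1:
        return False
    pat = s // 2
    oa = _ALLELES[o]
    if pat not in oa:
        return False
    rest = list(oa)
    rest.remove(pat)
    return rest[0] in da


def trio_inconsistency(sire: int, dam: int, off: int, off_sex: str, model: str) -> str:
    """Classify one trio of codes under an inheritance model.

    Returns ``"consistent"``, ``"inconsistent"`` or ``"uninformative"``
    (any missing member, or unknown offspring sex under the heterosomal
    model, is uninformative).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    for code in (sire, dam, off):
        if code not in (MISSING, 0, 1, 2):
            raise ValueError(f"invalid genotype code {code!r}")
    if MISSING in (sire, dam, off):
        return UNINFORMATIVE
    if model == PSEUDOAUTOSOMAL:
        return CONSISTENT if _pseudo_ok(sire, dam, off) else INCONSISTENT
    if off_sex not in (MALE, FEMALE):
        return UNINFORMATIVE
    return CONSISTENT if _hetero_ok(sire, dam, off, off_sex) else INCONSISTENT


def _build_tables():
    """Lookup tables indexed [sire+1, dam+1, off+1] (missing -> 0)."""
    shape = (4, 4, 4)
    pseudo = np.full(shape, 2, dtype=np.int8)  # 0 cons, 1 inc, 2 uninf
    het_m = np.full(shape, 2, dtype=np.int8)
    het_f = np.full(shape, 2, dtype=np.int8)
    for s in (0, 1, 2):
        for d in (0, 1, 2):
            for o in (0, 1, 2):
                ix = (s + 1, d + 1, o + 1)
                pseudo[ix] = 0 if _pseudo_ok(s, d, o) else 1
                het_m[ix] = 0 if _hetero_ok(s, d, o, MALE) else 1
                het_f[ix] = 0 if _hetero_ok(s, d, o, FEMALE) else 1
    return pseudo, het_m, het_f


_PSEUDO_TAB, _HET_M_TAB, _HET_F_TAB = _build_tables()


def inconsistency_counts(trioset: TrioSet):
    """Vectorized per-marker (inconsistent, informative) counts, both models.

    Returns ``(inc_pseudo, n_pseudo, inc_hetero, n_hetero)`` arrays.
    """
    calls = trioset.genotypes.calls
    s = calls[:, trioset.sire_idx] + 1
    d = calls[:, trioset.dam_idx] + 1
    o = calls[:, trioset.off_idx] + 1
    male = (trioset.off_sex == MALE)[None, :]
    female = (trioset.off_sex == FEMALE)[None, :]

    p = _PSEUDO_TAB[s, d, o]
    inc_p = (p == 1).sum(axis=1)
    n_p = (p != 2).sum(axis=1)

    hm = _HET_M_TAB[s, d, o]
    hf = _HET_F_TAB[s, d, o]
    inc_h = ((hm == 1) & male).sum(axis=1) + ((hf == 1) & female).sum(axis=1)
    n_h = ((hm != 2) & male).sum(axis=1) + ((hf != 2) & female).sum(axis=1)
    return inc_p, n_p, inc_h, n_h


@dataclass
class MarkerClassification:
    marker_id: str
    n_trios: int
    inc_pseudo: float
    inc_hetero: float
    male_het_rate: float
    label: str
    segment: int = -1


def classify_markers(
    trioset: TrioSet,
    high_inc: float = 0.05,
    null_inc: float = 0.01,
    k_neighbors: int = 2,
) -> list[MarkerClassification]:
    """Label every marker pseudoautosomal/heterosomal from trio inconsistencies.

    A marker is heterosomal when its inconsistency rate is below ``null_inc``
    under the heterosomal rule and at least ``high_inc`` under the
    pseudoautosomal rule, and symmetrically; anything else (including markers
    with no informative trios) is undetermined.  A determinate marker whose
    label contradicts the unanimous label of its determinate neighbours
    (``k_neighbors`` each side, needing at least two) is relabelled
    ``discordant-removed``.  Contiguous runs of equal labels among the
    surviving determinate markers receive consecutive segment ids.
    """
    inc_p, n_p, inc_h, n_h = inconsistency_counts(trioset)
    n_complete = trioset.n_complete_trios()

    calls = trioset.genotypes.calls
    male_cols = trioset.genotypes.sex == MALE
    if male_cols.any():
        mc = calls[:, male_cols]
        called = mc != MISSING
        with np.errstate(invalid="ignore"):
            male_het = np.where(
                called.sum(axis=1) > 0,
                (mc == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
                np.nan,
            )
    else:
        male_het = np.full(len(n_complete), np.nan)

    labels = []
    for m in range(len(n_complete)):
        rp = inc_p[m] / n_p[m] if n_p[m] else np.nan
        rh = inc_h[m] / n_h[m] if n_h[m] else np.nan
        if n_p[m] == 0 and n_h[m] == 0:
            labels.append(UNDETERMINED)
        elif not np.isnan(rh) and rh < null_inc and not np.isnan(rp) and rp >= high_inc:
            labels.append(HETEROSOMAL)
        elif not np.isnan(rp) and rp < null_inc and not np.isnan(rh) and rh >= high_inc:
            labels.append(PSEUDOAUTOSOMAL)
        else:
            labels.append(UNDETERMINED)

    # neighbour-consensus discordance removal (per chromosome, in map order)
    chrom = trioset.markers.chrom
    final = list(labels)
    for m, lab in enumerate(labels):
        if lab not in (PSEUDOAUTOSOMAL, HETEROSOMAL):
            continue
        neigh = []
        for step in (-1, 1):
            found = 0
            j = m + step
            while 0 <= j < len(labels) and found < k_neighbors:
                if chrom[j] != chrom[m]:
                    break
                if labels[j] in (PSEUDOAUTOSOMAL, HETEROSOMAL):
                    neigh.append(labels[j])
                    found += 1
                j += step
        if len(neigh) >= 2 and all(x != lab for x in neigh) and len(set(neigh)) == 1:
            final[m] = DISCORDANT

    # segmentation over determinate labels
    segments = [-1] * len(final)
    seg = -1
    prev = None
    for m, lab in enumerate(final):
        if lab in (PSEUDOAUTOSOMAL, HETEROSOMAL):
            key = (chrom[m], lab)
            if key != prev:
                seg += 1
                prev = key
            segments[m] = seg
        else:
            # undetermined/discordant markers break nothing but carry no segment
            pass

    out = []
    for m in range(len(final)):
        rp = inc_p[m] / n_p[m] if n_p[m] else np.nan
        rh = inc_h[m] / n_h[m] if n_h[m] else np.nan
        out.append(
            MarkerClassification(
                marker_id=trioset.markers.marker_id[m],
                n_trios=int(n_complete[m]),
                inc_pseudo=float(rp) if not np.isnan(rp) else np.nan,
                inc_hetero=float(rh) if not np.isnan(rh) else np.nan,
                male_het_rate=float(male_het[m]),
                label=final[m],
                segment=segments[m],
            )
        )
    return out


def apply_qc(
    classifications: list[MarkerClassification],
    min_trios: int = 100,
    max_inc: float = 0.01,
) -> list[int]:
    """Indices of markers passing the TRD-scan quality filters.

    Retains determinate markers with at least ``min_trios`` complete trios and
    an inconsistency rate under their assigned model below ``max_inc``.  The
    preliminary intake uses ``min_trios=10``.
    """
    keep = []
    for m, c in enumerate(classifications):
        if c.label == HETEROSOMAL:
            rate = c.inc_hetero
        elif c.label == PSEUDOAUTOSOMAL:
            rate = c.inc_pseudo
        else:
            continue
        if c.n_trios >= min_trios and not np.isnan(rate) and rate < max_inc:
            keep.append(m)
    return keep
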