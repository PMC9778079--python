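"""Reduce trio genotypes to TRD sufficient statistics.

At a biallelic marker (or a recoded haplotype pseudo-marker) every informative
transmission comes from a heterozygous parent; the counts of transmitted A
versus B alleles per parent and offspring sex, plus the ambiguous AB x AB ->
AB class, are sufficient for the allelic TRD models.  The mating-genotype
tables keep the raw per-mating offspring-genotype counts used by the
genotypic (recessive) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trio_data import MISSING, MALE, FEMALE, TrioSet
from .regions import PSEUDOAUTOSOMAL, HETEROSOMAL

POOLED = "pooled"


@dataclass
class TransmissionCounts:
    """Informative A/B transmission tallies for one marker and stratum."""

    n_a_dam: int = 0
    n_b_dam: int = 0
    n_a_sire: int = 0
    n_b_sire: int = 0
    n_ambiguous: int = 0
    n_het_dams: int = 0
    n_het_sires: int = 0
    n_informative: int = 0
    stratum: str = POOLED
    n_inconsistent: int = 0

    def __post_init__(self) -> None:
        for f in ("n_a_dam", "n_b_dam", "n_a_sire", "n_b_sire",
                  "n_ambiguous", "n_het_dams", "n_het_sires", "n_informative"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def n_dam(self) -> int:
        return self.n_a_dam + self.n_b_dam

    @property
    def n_sire(self) -> int:
        return self.n_a_sire + self.n_b_sire


@dataclass
class MatingGenotypeTable:
    """Offspring-genotype counts per (sire class x dam class) mating.

    ``classes`` maps a mating label, e.g. ``("A", "AB")`` for a hemizygous-A
    sire by heterozygous dam, to a length-3 count vector over offspring
    genotypes (AA, AB, BB).  Row sums equal the informative offspring of that
    mating class.
    """

    classes: dict = field(default_factory=dict)
    stratum: str = POOLED

    def add(self, key, off_code: int, k: int = 1) -> None:
        if key not in self.classes:
            self.classes[key] = np.zeros(3, dtype=np.int64)
        self.classes[key][off_code] += k

    def total(self) -> int:
        return int(sum(v.sum() for v in self.classes.values()))


def _stratum_mask(trioset: TrioSet, stratum: str) -> np.ndarray:
    if stratum == POOLED:
        return np.ones(len(trioset), dtype=bool)
    if stratum in (MALE, FEMALE):
        return trioset.off_sex == stratum
    raise ValueError(f"unknown stratum {stratum!r}")


def _check_label(labels, marker: int, wanted: str) -> None:
    if labels is None:
        return
    lab = labels[marker].label if hasattr(labels[marker], "label") else labels[marker]
    if lab != wanted:
        raise ValueError(f"marker index {marker} is labeled {lab!r}, not {wanted!r}")


# ---------------------------------------------------------------------------
# array-level core (also used for haplotype pseudo-markers)


def dam_counts_heterosomal_arrays(
    sire: np.ndarray,
    dam: np.ndarray,
    off: np.ndarray,
    off_sex: np.ndarray,
    dam_ids: np.ndarray | None = None,
    stratum: str = POOLED,
) -> TransmissionCounts:
    """Dam A/B transmission counts at a heterosomal (pseudo-)marker.

    Male offspring resolve the maternal allele directly (0 -> A, 2 -> B; a
    heterozygous male call is inconsistent).  Female offspring need a
    genotyped hemizygous sire: with sire A, offspring 0 -> dam A, 1 -> dam B;
    with sire B, offspring 1 -> dam A, 2 -> dam B; anything else is
    inconsistent.  Only heterozygous dams contribute.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    off = np.asarray(off)
    off_sex = np.asarray(off_sex, dtype=object)

    if stratum == POOLED:
        sel = np.ones(len(off), dtype=bool)
    else:
        sel = off_sex == stratum
    sel = sel & (dam == 1) & (off != MISSING)

    male = sel & (off_sex == MALE)
    female = sel & (off_sex == FEMALE) & (sire != MISSING)

    a = np.zeros(len(off), dtype=bool)
    b = np.zeros(len(off), dtype=bool)
    inc = np.zeros(len(off), dtype=bool)

    a |= male & (off == 0)
    b |= male & (off == 2)
    inc |= male & (off == 1)

    f_sire_a = female & (sire == 0)
    f_sire_b = female & (sire == 2)
    a |= f_sire_a & (off == 0)
    b |= f_sire_a & (off == 1)
    inc |= f_sire_a & (off == 2)
    a |= f_sire_b & (off == 1)
    b |= f_sire_b & (off == 2)
    inc |= f_sire_b & (off == 0)
    inc |= female & (sire == 1)

    counted = a | b
    if dam_ids is not None:
        n_het_dams = len(set(np.asarray(dam_ids, dtype=object)[counted]))
    else:
        n_het_dams = int(counted.sum())
    return TransmissionCounts(
        n_a_dam=int(a.sum()),
        n_b_dam=int(b.sum()),
        n_het_dams=n_het_dams,
        n_informative=int(counted.sum()),
        n_inconsistent=int(inc.sum()),
        stratum=stratum,
    )


def parent_counts_pseudoautosomal_arrays(
    sire: np.ndarray,
    dam: np.ndarray,
    off: np.ndarray,
    off_sex: np.ndarray,
    sire_ids: np.ndarray | None = None,
    dam_ids: np.ndarray | None = None,
    stratum: str = POOLED,
) -> tuple[TransmissionCounts, MatingGenotypeTable]:
    """Sire and dam transmission counts at a pseudoautosomal (pseudo-)marker.

    Matings with exactly one heterozygous parent resolve that parent's
    transmitted allele from the offspring genotype.  AB x AB matings resolve
    both parents for AA/BB offspring; AB offspring enter the ambiguous class
    (a mixture term in the likelihood, never a fractional count).
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    off = np.asarray(off)
    off_sex = np.asarray(off_sex, dtype=object)

    if stratum == POOLED:
        sel = np.ones(len(off), dtype=bool)
    else:
        sel = off_sex == stratum
    sel = sel & (sire != MISSING) & (dam != MISSING) & (off != MISSING)

    c = TransmissionCounts(stratum=stratum)
    table = MatingGenotypeTable(stratum=stratum)
    a_s = b_s = a_d = b_d = amb = inc = 0
    het_sire_sel = np.zeros(len(off), dtype=bool)
    het_dam_sel = np.zeros(len(off), dtype=bool)

    _G = {0: "AA", 1: "AB", 2: "BB"}
    for i in np.nonzero(sel)[0]:
        s, d, o = int(sire[i]), int(dam[i]), int(off[i])
        table.add((_G[s], _G[d]), o)
        if s == 1 and d != 1:
            # offspring = sire gamete + dam's forced allele
            forced = d // 2
            g = o - forced
            if g in (0, 1):
                a_s += g == 0
                b_s += g == 1
                het_sire_sel[i] = True
            else:
                inc += 1
        elif d == 1 and s != 1:
            forced = s // 2
            g = o - forced
            if g in (0, 1):
                a_d += g == 0
                b_d += g == 1
                het_dam_sel[i] = True
            else:
                inc += 1
        elif s == 1 and d == 1:
            het_sire_sel[i] = True
            het_dam_sel[i] = True
            if o == 0:
                a_s += 1
                a_d += 1
            elif o == 2:
                b_s += 1
                b_d += 1
            else:
                amb += 1
        # both parents homozygous: uninformative (consistency handled upstream)

    c.n_a_sire, c.n_b_sire = int(a_s), int(b_s)
    c.n_a_dam, c.n_b_dam = int(a_d), int(b_d)
    c.n_ambiguous = int(amb)
    c.n_inconsistent = int(inc)
    c.n_informative = int(a_s + b_s + a_d + b_d + amb)
    if sire_ids is not None:
        c.n_het_sires = len(set(np.asarray(sire_ids, dtype=object)[het_sire_sel]))
    else:
        c.n_het_sires = int(het_sire_sel.sum())
    if dam_ids is not None:
        c.n_het_dams = len(set(np.asarray(dam_ids, dtype=object)[het_dam_sel]))
    else:
        c.n_het_dams = int(het_dam_sel.sum())
    return c, table


def recessive_counts_arrays(
    sire: np.ndarray,
    dam: np.ndarray,
    off: np.ndarray,
    off_sex: np.ndarray,
) -> MatingGenotypeTable:
    """Female-offspring genotype counts per mating class, heterosomal region.

    Only heterozygous dams and genotyped hemizygous sires contribute; the
    sire class is its hemizygous allele ("A" or "B").  Offspring genotypes
    incompatible with the mating are excluded.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    off = np.asarray(off)
    off_sex = np.asarray(off_sex, dtype=object)

    sel = (off_sex == FEMALE) & (dam == 1) & (off != MISSING) & np.isin(sire, (0, 2))
    table = MatingGenotypeTable(stratum=FEMALE)
    for i in np.nonzero(sel)[0]:
        s, o = int(sire[i]), int(off[i])
        if s == 0 and o in (0, 1):
            table.add(("A", "AB"), o)
        elif s == 2 and o in (1, 2):
            table.add(("B", "AB"), o)
    return table


def heterosomal_mating_arrays(a_x_ab=(0, 0, 0), b_x_ab=(0, 0, 0),
                              sex: str = POOLED):
    """Expand printed heterosomal mating-genotype counts into trio arrays.

    ``a_x_ab`` holds offspring counts (AA/A, AB, B) for hemizygous-A sire x
    heterozygous dam matings, ``b_x_ab`` the (A, AB, BB/B) counts for
    hemizygous-B sires — the column layout used in published per-marker
    tables.  The merged homozygous-appearance columns are emitted as male
    offspring and the AB columns as female (the only consistent
    assignments); with ``sex`` = "male"/"female" all offspring get that sex
    (the AB column must then be empty for "male").
    """
    rows = []  # (sire, off, sex)
    def emit_class(sire_code, cols, codes):
        for count, off_code in zip(cols, codes):
            if sex == POOLED:
                off_sex = FEMALE if off_code == 1 else MALE
            else:
                off_sex = sex
            if sex == MALE and off_code == 1 and count:
                raise ValueError("male offspring cannot be heterozygous "
                                 "at a heterosomal marker")
            rows.extend([(sire_code, off_code, off_sex)] * int(count))

    emit_class(0, a_x_ab, (0, 1, 2))
    emit_class(2, b_x_ab, (0, 1, 2))
    if rows:
        sire, off, off_sex = map(np.array, zip(*rows))
    else:
        sire = off = np.array([], dtype=int)
        off_sex = np.array([], dtype=object)
    dam = np.ones(len(rows), dtype=np.int8)
    return sire.astype(np.int8), dam, off.astype(np.int8), off_sex.astype(object)


# ---------------------------------------------------------------------------
# marker-level wrappers


def dam_transmissions_heterosomal(
    trioset: TrioSet, marker: int, stratum: str = POOLED, labels=None
) -> TransmissionCounts:
    """Dam transmissions at a heterosomal marker of a trio set."""
    _check_label(labels, marker, HETEROSOMAL)
    s, d, o = trioset.calls_at(marker)
    return dam_counts_heterosomal_arrays(
        s, d, o, trioset.off_sex, dam_ids=trioset.dam_id, stratum=stratum
    )


def parent_transmissions_pseudoautosomal(
    trioset: TrioSet, marker: int, stratum: str = POOLED, labels=None
):
    """Sire/dam transmissions + mating table at a pseudoautosomal marker."""
    _check_label(labels, marker, PSEUDOAUTOSOMAL)
    s, d, o = trioset.calls_at(marker)
    return parent_counts_pseudoautosomal_arrays(
        s, d, o, trioset.off_sex,
        sire_ids=trioset.sire_id, dam_ids=trioset.dam_id, stratum=stratum,
    )


def recessive_category_counts(
    trioset: TrioSet, marker: int, labels=None
) -> MatingGenotypeTable:
    """Female-offspring mating-genotype table at a heterosomal marker."""
    _check_label(labels, marker, HETEROSOMAL)
    s, d, o = trioset.calls_at(marker)
    return recessive_counts_arrays(s, d, o, trioset.off_sex)
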