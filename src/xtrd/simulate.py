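"""Forward simulator of sex-chromosome trio genotypes with configurable TRD.

The simulator emulates the mechanisms the analysis targets:

* dams transmit one X per offspring, with optional allele-level distortion
  (per-marker dam alpha, optionally stratified by offspring sex);
* sires transmit X to daughters and Y to sons; within the pseudoautosomal
  region (PAR) the transmitted chromatid is a recombinant mosaic of the
  sire's X- and Y-borne PAR haplotypes under a genetic map whose distance
  grows away from the pseudoautosomal boundary — which generates the
  opposite-sign sire-TRD pattern between offspring sexes that decays with
  distance from the boundary;
* the heterosomal sire region transmits without recombination and male
  offspring are emitted array-style (0/2) there;
* a recessive-lethal haplotype removes homozygous female offspring before
  sampling reaches the requested family sizes;
* genotyping error and missingness are applied last.

Population-level sire-TRD arises by fixing a configurable fraction of sires
with the same Y-linked PAR haplotype (population X/Y linkage), since alpha
is a population parameter while phase is per-sire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.random import default_rng

from .trio_data import (
    MISSING, MALE, FEMALE, MarkerMap, GenotypeTable, TrioSet,
    assemble_trios,
)
from .regions import HETEROSOMAL, PSEUDOAUTOSOMAL


@dataclass
class SimConfig:
    """Study design, marker grid, genetic maps and injected TRD.

    ``allele_freq`` is the population frequency of allele A (scalar or
    per-marker array).  ``dam_trd`` maps marker index ->
    ``{"pooled": alpha}`` or ``{"male": a, "female": a}``; alpha is the
    deviation of P(transmit A) from 0.5 among heterozygous dams.
    ``sire_y_ref_fraction`` is the fraction of sires whose Y-borne PAR
    haplotype is the all-A reference haplotype.  Map lengths are in Morgans.
    """

    n_sires: int = 200
    n_trios: int = 5000
    sex_ratio: float = 0.5
    n_het_markers: int = 500
    n_par_markers: int = 100
    het_span: tuple = (29_245, 137_034_696)
    par_span: tuple = (143_865_210, 148_816_634)
    chrom: str = "X"
    allele_freq: float | np.ndarray = 0.5
    par_map_length: float = 1.0
    dam_map_length: float = 1.0
    sire_y_ref_fraction: float = 1.0
    dam_trd: dict = field(default_factory=dict)
    dam_hap_trd: tuple = ()  # ((marker_indices, haplotype, alpha), ...)
    founder_ld_scale: float = 0.0  # >0: population LD decaying with map distance
    lethal_markers: tuple = ()
    lethal_haplotype: tuple = ()
    genotyping_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.sex_ratio, self.sire_y_ref_fraction,
                  self.genotyping_error, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for a in self.dam_trd.values():
            for v in a.values():
                if not -0.5 <= v <= 0.5:
                    raise ValueError("dam alpha must be in [-0.5, 0.5]")
        for mk, hp, a in self.dam_hap_trd:
            if len(mk) != len(hp):
                raise ValueError("haplotype TRD: markers/haplotype mismatch")
            if not -0.5 <= a <= 0.5:
                raise ValueError("haplotype alpha must be in [-0.5, 0.5]")
        if len(self.lethal_markers) != len(self.lethal_haplotype):
            raise ValueError("lethal_markers and lethal_haplotype lengths differ")
        if self.n_het_markers < 0 or self.n_par_markers < 0:
            raise ValueError("marker counts must be >= 0")

    @property
    def n_markers(self) -> int:
        return self.n_het_markers + self.n_par_markers

    def marker_map(self) -> MarkerMap:
        het = np.linspace(*self.het_span, self.n_het_markers).astype(np.int64) \
            if self.n_het_markers else np.array([], dtype=np.int64)
        par = np.linspace(*self.par_span, self.n_par_markers).astype(np.int64) \
            if self.n_par_markers else np.array([], dtype=np.int64)
        pos = np.concatenate([het, par])
        n = len(pos)
        return MarkerMap(
            marker_id=np.array([f"snp{i:05d}" for i in range(n)], dtype=object),
            chrom=np.array([self.chrom] * n, dtype=object),
            pos=pos,
            allele_a=np.array(["A"] * n, dtype=object),
            allele_b=np.array(["B"] * n, dtype=object),
        )

    def true_labels(self) -> np.ndarray:
        return np.array(
            [HETEROSOMAL] * self.n_het_markers
            + [PSEUDOAUTOSOMAL] * self.n_par_markers, dtype=object
        )

    def freq_a(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.allele_freq, dtype=float),
                            (self.n_markers,)).copy()
        if np.any((f < 0) | (f > 1)):
            raise ValueError("allele_freq must be in [0, 1]")
        return f


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated genotypes."""

    labels: np.ndarray            # true region label per marker
    sire_x: np.ndarray            # (n_markers, n_sires) allele codes 0/1
    sire_y_par: np.ndarray        # (n_par, n_sires)
    dam_h1: np.ndarray
    dam_h2: np.ndarray
    maternal: np.ndarray          # (n_markers, n_trios) transmitted dam allele
    paternal: np.ndarray          # (n_markers, n_trios); -2 where absent
    n_recomb_dam: np.ndarray
    n_recomb_sire: np.ndarray
    dam_trd: dict
    config: SimConfig


def _mosaic(h0: np.ndarray, h1: np.ndarray, gpos: np.ndarray,
            length: float, start: int, rng) -> tuple[np.ndarray, np.ndarray, int]:
    """Recombinant of two haplotypes; returns (gamete, complement, n_xo)."""
    n_xo = rng.poisson(length)
    if n_xo == 0:
        src = np.full(len(gpos), start, dtype=np.int8)
    else:
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        crossings = np.searchsorted(xo, gpos, side="right")
        src = ((start + crossings) % 2).astype(np.int8)
    gam = np.where(src == 0, h0, h1)
    comp = np.where(src == 0, h1, h0)
    return gam, comp, int(n_xo)


def simulate(cfg: SimConfig, seed: int | None = None) -> tuple[TrioSet, SimTruth]:
    """Simulate trio genotypes; returns the TrioSet and its ground truth."""
    rng = default_rng(cfg.seed if seed is None else seed)
    n_mark = cfg.n_markers
    n_het = cfg.n_het_markers
    markers = cfg.marker_map()
    freq_a = cfg.freq_a()
    p_b = 1.0 - freq_a

    n_sires, n_trios = cfg.n_sires, cfg.n_trios

    pos = markers.pos.astype(float)
    # dam meiosis: uniform map across the whole X
    span = pos[-1] - pos[0] if n_mark > 1 else 1.0
    gpos_dam = (pos - pos[0]) / span * cfg.dam_map_length
    # sire PAR meiosis: map distance grows away from the boundary
    if n_mark > n_het:
        par_pos = pos[n_het:]
        par_span = par_pos[-1] - par_pos[0] if len(par_pos) > 1 else 1.0
        gpos_par = (par_pos - par_pos[0]) / par_span * cfg.par_map_length
    else:
        gpos_par = np.array([])

    def founder(n_cols: int) -> np.ndarray:
        """Founder haplotypes (codes: 0 = A, 1 = B).

        With founder_ld_scale > 0, adjacent alleles are copied with
        probability exp(-scale * map distance); the PAR accumulates extra
        (male) map distance, so its population LD decays faster.
        """
        fresh = (rng.random((n_mark, n_cols)) < p_b[:, None]).astype(np.int8)
        if cfg.founder_ld_scale <= 0 or n_mark < 2:
            return fresh
        dg = np.diff(gpos_dam)
        if len(gpos_par) > 1:
            dg[n_het:] += np.diff(gpos_par)
        if n_mark > n_het > 0:
            dg[n_het - 1] = np.inf  # regions are unlinked pools
        cprob = np.exp(-cfg.founder_ld_scale * dg)
        h = fresh.copy()
        for j in range(1, n_mark):
            copy = rng.random(n_cols) < cprob[j - 1]
            h[j, copy] = h[j - 1, copy]
        return h

    sire_x = founder(n_sires)
    y_par = founder(n_sires)[n_het:]
    ref_y = rng.random(n_sires) < cfg.sire_y_ref_fraction
    y_par[:, ref_y] = 0  # reference Y-PAR haplotype: all allele A
    dam_h1 = founder(n_trios)
    dam_h2 = founder(n_trios)

    sire_of = np.arange(n_trios) % n_sires
    off_sex = np.empty(n_trios, dtype=object)

    maternal = np.empty((n_mark, n_trios), dtype=np.int8)
    paternal = np.full((n_mark, n_trios), -2, dtype=np.int8)
    n_recomb_dam = np.zeros(n_trios, dtype=np.int32)
    n_recomb_sire = np.zeros(n_trios, dtype=np.int32)

    trd_items = sorted(cfg.dam_trd.items())
    lethal = np.array(cfg.lethal_haplotype, dtype=np.int8)
    lmark = np.array(cfg.lethal_markers, dtype=np.intp)

    for i in range(n_trios):
        s = sire_of[i]
        for _attempt in range(1000):
            # sex is part of the rejection draw: a carrier x carrier mating
            # can only contribute surviving male offspring
            sex = MALE if rng.random() < cfg.sex_ratio else FEMALE
            start = int(rng.random() < 0.5)
            gam, comp, nxo = _mosaic(dam_h1[:, i], dam_h2[:, i], gpos_dam,
                                     cfg.dam_map_length, start, rng)
            # dam TRD at the first applicable focal marker or haplotype:
            # choose between the two complementary gametes of the meiosis
            applied = False
            for mk, hp, a in cfg.dam_hap_trd:
                mk = np.asarray(mk, dtype=np.intp)
                hp = np.asarray(hp, dtype=np.int8)
                g_is = bool(np.all(gam[mk] == hp))
                c_is = bool(np.all(comp[mk] == hp))
                if g_is != c_is:  # dam heterozygous for the haplotype
                    want_h = rng.random() < 0.5 + a
                    if g_is != want_h:
                        gam, comp = comp, gam
                    applied = True
                    break
            if not applied:
                for m, alphas in trd_items:
                    a = alphas.get(sex, alphas.get("pooled"))
                    if a is None:
                        continue
                    if gam[m] != comp[m]:
                        want_a = rng.random() < 0.5 + a
                        if (gam[m] == 0) != want_a:
                            gam, comp = comp, gam
                        break
            mat = gam

            if sex == MALE:
                pat = np.full(n_mark, -2, dtype=np.int8)
                if len(gpos_par):
                    g, _, nxo_s = _mosaic(y_par[:, s], sire_x[n_het:, s],
                                          gpos_par, cfg.par_map_length, 0, rng)
                    pat[n_het:] = g
                else:
                    nxo_s = 0
            else:
                pat = sire_x[:, s].copy()
                if len(gpos_par):
                    g, _, nxo_s = _mosaic(sire_x[n_het:, s], y_par[:, s],
                                          gpos_par, cfg.par_map_length, 0, rng)
                    pat[n_het:] = g
                else:
                    nxo_s = 0

            if len(lmark) and sex == FEMALE:
                if (np.all(mat[lmark] == lethal)
                        and np.all(pat[lmark] == lethal)):
                    continue  # lethal homozygote: resample this offspring
            break
        off_sex[i] = sex
        maternal[:, i] = mat
        paternal[:, i] = pat
        n_recomb_dam[i] = nxo
        n_recomb_sire[i] = nxo_s

    # emitted genotype codes (count of allele B)
    sire_calls = np.empty((n_mark, n_sires), dtype=np.int8)
    sire_calls[:n_het] = 2 * sire_x[:n_het]  # hemizygous, array-style
    sire_calls[n_het:] = sire_x[n_het:] + y_par
    dam_calls = (dam_h1 + dam_h2).astype(np.int8)
    off_calls = np.empty((n_mark, n_trios), dtype=np.int8)
    male = off_sex == MALE
    off_calls[:n_het][:, male] = 2 * maternal[:n_het][:, male]
    off_calls[n_het:][:, male] = (maternal[n_het:][:, male]
                                  + paternal[n_het:][:, male])
    off_calls[:, ~male] = maternal[:, ~male] + paternal[:, ~male]

    calls = np.concatenate([sire_calls, dam_calls, off_calls], axis=1)

    if cfg.genotyping_error > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < cfg.missing_rate,
                         MISSING, calls).astype(np.int8)

    ids = (
        [f"S{j:04d}" for j in range(n_sires)]
        + [f"D{j:05d}" for j in range(n_trios)]
        + [f"O{j:05d}" for j in range(n_trios)]
    )
    sex_arr = np.array(
        [MALE] * n_sires + [FEMALE] * n_trios + list(off_sex), dtype=object
    )
    gt = GenotypeTable(ids=ids, sex=sex_arr, calls=calls, markers=markers)
    pedigree = [
        (f"O{j:05d}", f"S{sire_of[j]:04d}", f"D{j:05d}", off_sex[j])
        for j in range(n_trios)
    ]
    trioset = assemble_trios(gt, pedigree)
    truth = SimTruth(
        labels=cfg.true_labels(),
        sire_x=sire_x,
        sire_y_par=y_par,
        dam_h1=dam_h1,
        dam_h2=dam_h2,
        maternal=maternal,
        paternal=paternal,
        n_recomb_dam=n_recomb_dam,
        n_recomb_sire=n_recomb_sire,
        dam_trd=dict(cfg.dam_trd),
        config=cfg,
    )
    return trioset, truth


def emit(trioset: TrioSet, truth: SimTruth, out_dir) -> dict:
    """Write PED/MAP, pedigree TSV and truth TSV; returns the paths.

    Re-reading the PED/MAP with :func:`~xtrd.trio_data.read_genotypes` and
    re-assembling with the pedigree reproduces the trio set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = trioset.genotypes
    markers = gt.markers
    paths = {
        "ped": out / "sim.ped",
        "map": out / "sim.map",
        "pedigree": out / "pedigree.tsv",
        "truth": out / "truth.tsv",
    }
    with open(paths["map"], "w") as fh:
        for m in range(len(markers)):
            fh.write(f"{markers.chrom[m]}\t{markers.marker_id[m]}\t0\t"
                     f"{markers.pos[m]}\n")
    sex_code = {MALE: "1", FEMALE: "2"}
    parent = {}
    for off, sire, dam in zip(trioset.offspring_id, trioset.sire_id,
                              trioset.dam_id):
        parent[off] = (sire, dam)
    with open(paths["ped"], "w") as fh:
        for j, iid in enumerate(gt.ids):
            sire, dam = parent.get(iid, ("0", "0"))
            fields = ["FAM", str(iid), str(sire), str(dam),
                      sex_code.get(gt.sex[j], "0"), "-9"]
            for m in range(len(markers)):
                c = gt.calls[m, j]
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    a, b = markers.allele_a[m], markers.allele_b[m]
                    fields += [b if c >= 1 else a, b if c == 2 else a]
            fh.write(" ".join(fields) + "\n")
    with open(paths["pedigree"], "w") as fh:
        fh.write("offspring_id\tsire_id\tdam_id\toffspring_sex\n")
        for off, sire, dam, sex in zip(trioset.offspring_id, trioset.sire_id,
                                       trioset.dam_id, trioset.off_sex):
            fh.write(f"{off}\t{sire}\t{dam}\t{sex}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("offspring_id\tn_recomb_dam\tn_recomb_sire_par\n")
        for off, nd, ns in zip(trioset.offspring_id, truth.n_recomb_dam,
                               truth.n_recomb_sire):
            fh.write(f"{off}\t{nd}\t{ns}\n")
    return paths
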