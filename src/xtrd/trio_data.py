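"""Marker maps, genotype tables and trio assembly.

Genotype calls are coded as the number of copies of allele B: ``0`` = A/A,
``1`` = A/B, ``2`` = B/B, ``-1`` = missing.  Hemizygous males at heterosomal
markers are represented array-style as ``0`` or ``2`` (homozygous appearance),
which is how SNP arrays report the X; a male ``1`` call there is treated
downstream as evidence against heterosomal inheritance, never silently fixed.

Coordinates are 1-based inclusive base pairs.  Missing genotypes are never
imputed here; downstream computations skip incomplete trios individually.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"


@dataclass
class MarkerMap:
    """Ordered markers with 1-based bp positions and single-character alleles."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        n = len(self.marker_id)
        for name in ("chrom", "pos", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} has wrong length")
        if len(set(self.marker_id)) != n:
            raise ValueError("duplicate marker ids")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        same = self.allele_a == self.allele_b
        if np.any(same):
            bad = self.marker_id[same][0]
            raise ValueError(f"marker {bad}: allele_a == allele_b")

    def __len__(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class GenotypeTable:
    """Biallelic calls (markers x individuals) with per-individual sex."""

    ids: list
    sex: np.ndarray
    calls: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.sex = np.asarray(self.sex, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate individual id")
        if self.calls.shape != (len(self.markers), len(self.ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.ids)} individuals"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if np.any(bad):
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        ok_sex = np.isin(self.sex, (MALE, FEMALE, UNKNOWN))
        if not np.all(ok_sex):
            raise ValueError("sex must be male/female/unknown")
        self._index = {iid: j for j, iid in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, individual_id) -> np.ndarray:
        return self.calls[:, self._index[individual_id]]

    def index_of(self, individual_id) -> int:
        return self._index[individual_id]

    def __contains__(self, individual_id) -> bool:
        return individual_id in self._index

    def missing_rate(self) -> float:
        return float(np.mean(self.calls == MISSING))


@dataclass
class TrioSet:
    """Sire-dam-offspring triples joined to a genotype table.

    ``off_idx``/``sire_idx``/``dam_idx`` are column indices into
    ``genotypes.calls``; ``off_sex`` is the pedigree-stated offspring sex.
    """

    genotypes: GenotypeTable
    offspring_id: np.ndarray
    sire_id: np.ndarray
    dam_id: np.ndarray
    off_sex: np.ndarray
    off_idx: np.ndarray = field(default=None)
    sire_idx: np.ndarray = field(default=None)
    dam_idx: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        gt = self.genotypes
        self.offspring_id = np.asarray(self.offspring_id, dtype=object)
        self.sire_id = np.asarray(self.sire_id, dtype=object)
        self.dam_id = np.asarray(self.dam_id, dtype=object)
        self.off_sex = np.asarray(self.off_sex, dtype=object)
        if self.off_idx is None:
            self.off_idx = np.array(
                [gt.index_of(i) for i in self.offspring_id], dtype=np.intp
            )
            self.sire_idx = np.array(
                [gt.index_of(i) for i in self.sire_id], dtype=np.intp
            )
            self.dam_idx = np.array(
                [gt.index_of(i) for i in self.dam_id], dtype=np.intp
            )
        for sid, stated in zip(self.sire_id, gt.sex[self.sire_idx]):
            if stated == FEMALE:
                raise ValueError(f"sire {sid} has stated sex female")
        for did, stated in zip(self.dam_id, gt.sex[self.dam_idx]):
            if stated == MALE:
                raise ValueError(f"dam {did} has stated sex male")

    def __len__(self) -> int:
        return len(self.offspring_id)

    @property
    def markers(self) -> MarkerMap:
        return self.genotypes.markers

    def calls_at(self, marker: int):
        """(sire, dam, offspring) code vectors at one marker index."""
        row = self.genotypes.calls[marker]
        return row[self.sire_idx], row[self.dam_idx], row[self.off_idx]

    def n_complete_trios(self) -> np.ndarray:
        """Per-marker count of trios with all three members called."""
        c = self.genotypes.calls
        ok = (
            (c[:, self.sire_idx] != MISSING)
            & (c[:, self.dam_idx] != MISSING)
            & (c[:, self.off_idx] != MISSING)
        )
        return ok.sum(axis=1)


# ---------------------------------------------------------------------------
# readers


def _parse_sex(code: str) -> str:
    return {"1": MALE, "2": FEMALE}.get(code, UNKNOWN)


def read_genotypes(path, format: str = "ped_map", map_path=None):
    """Read genotypes into a :class:`GenotypeTable` + :class:`MarkerMap`.

    format="ped_map": ``path`` is a prefix; ``<path>.ped`` and ``<path>.map``
    are read (whitespace-delimited PLINK text, allele "0" = missing).

    format="tsv": ``path`` is a tidy TSV with columns
    marker_id, individual_id, code (code in {0,1,2} or NA); ``map_path`` is a
    TSV with columns marker_id, chrom, pos, allele_a, allele_b.
    """
    if format == "ped_map":
        gt, markers = _read_ped_map(Path(str(path) + ".ped"), Path(str(path) + ".map"))
    elif format == "tsv":
        if map_path is None:
            raise ValueError("tsv format requires map_path")
        gt, markers = _read_tsv(Path(path), Path(map_path))
    else:
        raise ValueError(f"unknown format {format!r}")
    logger.info(
        "read %d individuals x %d markers, missing rate %.4f",
        gt.n_individuals, gt.n_markers, gt.missing_rate(),
    )
    return gt, markers


def _read_map(map_file: Path) -> tuple[list, list, list]:
    chroms, ids, poss = [], [], []
    with open(map_file) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ValueError(f"{map_file}:{lineno}: malformed MAP line")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[-1]))
    return chroms, ids, poss


def _read_ped_map(ped_file: Path, map_file: Path):
    chroms, ids, poss = _read_map(map_file)
    n_markers = len(ids)

    indiv_ids: list = []
    sexes: list = []
    allele_rows: list = []
    with open(ped_file) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_file}:{lineno}: expected {6 + 2 * n_markers} fields,"
                    f" got {len(parts)}"
                )
            iid = parts[1]
            if iid in indiv_ids:
                raise ValueError(f"{ped_file}:{lineno}: duplicate individual id {iid}")
            indiv_ids.append(iid)
            sexes.append(_parse_sex(parts[4]))
            allele_rows.append(parts[6:])

    # determine the two alleles per marker from observed characters
    n_ind = len(indiv_ids)
    a1 = np.empty((n_markers, n_ind), dtype=object)
    a2 = np.empty((n_markers, n_ind), dtype=object)
    for j, row in enumerate(allele_rows):
        a1[:, j] = row[0::2]
        a2[:, j] = row[1::2]

    allele_a, allele_b = [], []
    calls = np.full((n_markers, n_ind), MISSING, dtype=np.int8)
    for m in range(n_markers):
        observed = sorted((set(a1[m]) | set(a2[m])) - {"0"})
        if len(observed) > 2:
            raise ValueError(
                f"marker {ids[m]}: {len(observed)} observed alleles, expected <= 2"
            )
        aa = observed[0] if observed else "A"
        bb = observed[1] if len(observed) > 1 else ("B" if aa != "B" else "C")
        allele_a.append(aa)
        allele_b.append(bb)
        missing = (a1[m] == "0") | (a2[m] == "0")
        code = (a1[m] == bb).astype(np.int8) + (a2[m] == bb).astype(np.int8)
        code[missing] = MISSING
        calls[m] = code

    markers = MarkerMap(
        marker_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        allele_a=np.array(allele_a, dtype=object),
        allele_b=np.array(allele_b, dtype=object),
    )
    gt = GenotypeTable(ids=indiv_ids, sex=np.array(sexes, dtype=object),
                       calls=calls, markers=markers)
    return gt, markers


def _read_tsv(tsv_file: Path, map_file: Path):
    mp = pd.read_csv(map_file, sep="\t", dtype={"marker_id": str, "chrom": str})
    markers = MarkerMap(
        marker_id=mp["marker_id"].to_numpy(dtype=object),
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=mp["pos"].to_numpy(),
        allele_a=mp["allele_a"].to_numpy(dtype=object),
        allele_b=mp["allele_b"].to_numpy(dtype=object),
    )
    df = pd.read_csv(tsv_file, sep="\t", dtype={"marker_id": str, "individual_id": str})
    for col in ("marker_id", "individual_id", "code"):
        if col not in df.columns:
            raise ValueError(f"{tsv_file}: missing column {col!r}")
    unknown = set(df["marker_id"]) - set(markers.marker_id)
    if unknown:
        raise ValueError(f"{tsv_file}: markers not in map: {sorted(unknown)[:5]}")
    ids = list(dict.fromkeys(df["individual_id"]))
    midx = {m: i for i, m in enumerate(markers.marker_id)}
    iidx = {i: j for j, i in enumerate(ids)}
    calls = np.full((len(markers), len(ids)), MISSING, dtype=np.int8)
    codes = df["code"].to_numpy()
    rows = df["marker_id"].map(midx).to_numpy()
    cols = df["individual_id"].map(iidx).to_numpy()
    valid = pd.notna(codes)
    codes = np.where(valid, codes, MISSING).astype(np.int8)
    if np.any(~np.isin(codes, (MISSING, 0, 1, 2))):
        raise ValueError(f"{tsv_file}: codes must be 0/1/2 or NA")
    calls[rows, cols] = codes
    sex = np.array([UNKNOWN] * len(ids), dtype=object)
    if "sex" in df.columns:
        for iid, s in zip(df["individual_id"], df["sex"]):
            if s in (MALE, FEMALE):
                sex[iidx[iid]] = s
    gt = GenotypeTable(ids=ids, sex=sex, calls=calls, markers=markers)
    return gt, markers


# ---------------------------------------------------------------------------
# trio assembly


def assemble_trios(gt: GenotypeTable, pedigree: Iterable) -> TrioSet:
    """Join a pedigree of (offspring, sire, dam, sex) rows to genotypes.

    Trios with any ungenotyped member are dropped (count logged).  The order
    of pedigree rows does not affect the result beyond trio order, and trio
    order never affects downstream counts.
    """
    if isinstance(pedigree, pd.DataFrame):
        rows = list(
            pedigree[["offspring_id", "sire_id", "dam_id", "offspring_sex"]]
            .itertuples(index=False, name=None)
        )
    else:
        rows = [tuple(r) for r in pedigree]
    kept, dropped = [], 0
    for off, sire, dam, sex in rows:
        if off == sire or off == dam:
            raise ValueError(f"offspring {off} listed as its own parent")
        if off in gt and sire in gt and dam in gt:
            kept.append((off, sire, dam, sex))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d trios with ungenotyped members", dropped)
    if kept:
        off, sire, dam, sex = map(np.array, zip(*kept))
    else:
        off = sire = dam = sex = np.array([], dtype=object)
    return TrioSet(
        genotypes=gt,
        offspring_id=off.astype(object),
        sire_id=sire.astype(object),
        dam_id=dam.astype(object),
        off_sex=sex.astype(object),
    )


# ---------------------------------------------------------------------------
# result tables

#: columns written for every result row (missing values -> NA)
_RESULT_META = ["id", "chrom", "start_bp", "end_bp", "region", "stratum",
                "window_size", "random_trd_class", "n_underrepresented"]
_RESULT_COUNTS = ["n_a_dam", "n_b_dam", "n_a_sire", "n_b_sire", "n_ambiguous",
                  "n_het_dams", "n_het_sires", "n_informative",
                  "n_inconsistent"]


def write_results(results: Sequence, path, config_hash: str = "", seed=None) -> None:
    """Write TRD results as a TSV; layout mirrors the per-marker scan tables.

    A ``#`` header comment records the config hash and seed.  The file round
    trips through :func:`read_results`.
    """
    param_names: list[str] = []
    for r in results:
        for p in r.params:
            if p not in param_names:
                param_names.append(p)
    cols = list(_RESULT_META) + list(_RESULT_COUNTS)
    for p in param_names:
        cols += [f"{p}_mean", f"{p}_sd", f"{p}_log10_bf"]

    rows = []
    for r in results:
        row = {c: getattr(r, c, None) for c in _RESULT_META}
        counts = r.counts
        for c in _RESULT_COUNTS:
            row[c] = getattr(counts, c, None) if counts is not None else None
        for p in param_names:
            if p in r.params:
                row[f"{p}_mean"] = repr(float(r.params[p][0]))
                row[f"{p}_sd"] = repr(float(r.params[p][1]))
            if p in r.log10_bf:
                row[f"{p}_log10_bf"] = repr(float(r.log10_bf[p]))
        rows.append(row)

    df = pd.DataFrame(rows, columns=cols)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# xtrd results\tconfig_hash={config_hash}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results(path) -> list:
    """Read back a table written by :func:`write_results`."""
    from .inference import TrdResult
    from .transmissions import TransmissionCounts

    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     float_precision="round_trip")
    param_names = sorted(
        {c[: -len("_mean")] for c in df.columns if c.endswith("_mean")}
    )
    out = []
    for _, row in df.iterrows():
        params, bfs = {}, {}
        for p in param_names:
            if pd.notna(row.get(f"{p}_mean")):
                params[p] = (float(row[f"{p}_mean"]), float(row[f"{p}_sd"]))
            if pd.notna(row.get(f"{p}_log10_bf")):
                bfs[p] = float(row[f"{p}_log10_bf"])
        counts = None
        if pd.notna(row.get("n_informative")):
            counts = TransmissionCounts(
                **{c: int(row[c]) if pd.notna(row[c]) else 0
                   for c in _RESULT_COUNTS},
                stratum=row["stratum"] if pd.notna(row.get("stratum")) else "pooled",
            )
        out.append(
            TrdResult(
                id=row["id"],
                chrom=row["chrom"] if pd.notna(row.get("chrom")) else None,
                start_bp=int(row["start_bp"]) if pd.notna(row.get("start_bp")) else None,
                end_bp=int(row["end_bp"]) if pd.notna(row.get("end_bp")) else None,
                region=row["region"] if pd.notna(row.get("region")) else None,
                stratum=row["stratum"] if pd.notna(row.get("stratum")) else None,
                window_size=int(row["window_size"]) if pd.notna(row.get("window_size")) else None,
                params=params,
                log10_bf=bfs,
                random_trd_class=row["random_trd_class"]
                if pd.notna(row.get("random_trd_class")) else None,
                n_underrepresented=int(row["n_underrepresented"])
                if pd.notna(row.get("n_underrepresented")) else None,
                counts=counts,
            )
        )
    return out


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for output headers."""
    text = repr(sorted(str(obj).split()))
    return hashlib.sha256(text.encode()).hexdigest()[:12]
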