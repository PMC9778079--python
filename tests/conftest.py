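import numpy as np
import pytest

from xtrd import (
    GenotypeTable, MarkerMap, TrioSet, assemble_trios,
    SimConfig, simulate,
)


def make_markers(n, chrom="X", start=1000, step=1000):
    return MarkerMap(
        marker_id=np.array([f"m{i}" for i in range(n)], dtype=object),
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.arange(start, start + n * step, step, dtype=np.int64),
        allele_a=np.array(["A"] * n, dtype=object),
        allele_b=np.array(["B"] * n, dtype=object),
    )


def make_trioset(calls, sexes, pedigree, markers=None):
    """Build a TrioSet from a calls matrix and pedigree tuples."""
    calls = np.asarray(calls, dtype=np.int8)
    n_mark, n_ind = calls.shape
    ids = [f"i{j}" for j in range(n_ind)]
    gt = GenotypeTable(
        ids=ids,
        sex=np.array(sexes, dtype=object),
        calls=calls,
        markers=markers or make_markers(n_mark),
    )
    return assemble_trios(gt, pedigree)


@pytest.fixture(scope="session")
def mixed_sim():
    """Error-free mixed-region simulation used by several tests."""
    cfg = SimConfig(n_sires=60, n_trios=1500, n_het_markers=25,
                    n_par_markers=10, seed=101)
    trioset, truth = simulate(cfg)
    return cfg, trioset, truth


@pytest.fixture(scope="session")
def par_sim():
    """Pseudoautosomal-only simulation with full Y-linkage at the boundary."""
    cfg = SimConfig(n_sires=150, n_trios=4000, n_het_markers=0,
                    n_par_markers=25, par_map_length=2.0, seed=202)
    trioset, truth = simulate(cfg)
    return cfg, trioset, truth
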