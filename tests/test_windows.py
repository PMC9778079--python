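"""Phasing, biallelic window recoding, scans and consolidation."""

import numpy as np
import pytest

from xtrd import (
    SimConfig, simulate, phase_trios, scan_windows, consolidate,
    recessive_scan, dam_transmissions_heterosomal, McmcConfig,
    GenotypeTable, assemble_trios,
)
from xtrd.regions import HETEROSOMAL, PSEUDOAUTOSOMAL
from xtrd.windows import UNRESOLVED, ABSENT

from conftest import make_markers, make_trioset


SHORT_CHAIN = McmcConfig(iterations=8_000, burn_in=2_000, seed=5)


class TestPhasing:
    def test_pseudoautosomal_het_offspring_resolved_by_hom_parent(self):
        # offspring AB, sire AA, dam BB -> paternal A, maternal B
        calls = np.array([[0], [2], [1]]).T.reshape(1, 3).astype(np.int8)
        ts = make_trioset(calls, ["male", "female", "female"],
                          [("i2", "i0", "i1", "female")])
        ph = phase_trios(ts, labels=[PSEUDOAUTOSOMAL])
        assert ph.pat[0, 0] == 0 and ph.mat[0, 0] == 1

    def test_hemizygous_male_phases_trivially(self):
        calls = np.array([[2, 1, 0]], dtype=np.int8)
        ts = make_trioset(calls, ["male", "female", "male"],
                          [("i2", "i0", "i1", "male")])
        ph = phase_trios(ts)
        assert ph.mat[0, 0] == 0
        assert ph.pat[0, 0] == ABSENT

    def test_double_het_pseudoautosomal_unresolved(self):
        calls = np.array([[1, 1, 1]], dtype=np.int8)
        ts = make_trioset(calls, ["male", "female", "female"],
                          [("i2", "i0", "i1", "female")])
        ph = phase_trios(ts, labels=[PSEUDOAUTOSOMAL])
        assert ph.pat[0, 0] == UNRESOLVED

    def test_phased_maternal_equals_simulator_truth(self, mixed_sim):
        cfg, ts, truth = mixed_sim
        ph = phase_trios(ts, labels=list(truth.labels))
        resolved = ph.mat >= 0
        assert resolved.mean() > 0.8
        assert np.array_equal(ph.mat[resolved], truth.maternal[resolved])


class TestBiallelicRecoding:
    def test_three_haplotypes_give_three_pseudo_markers(self):
        # 2-SNP window with dam haplotype pool {AB, BA, AA}
        # dams: i2=AB/BA (calls 1,1), i3=BA/AA (1,0); sires hemizygous A
        calls = np.array(
            [[0, 0, 1, 1, 2, 0],
             [0, 0, 1, 0, 0, 0]], dtype=np.int8
        )
        sexes = ["male", "male", "female", "female", "male", "male"]
        ped = [("i4", "i0", "i2", "male"), ("i5", "i1", "i3", "male")]
        ts = make_trioset(calls, sexes, ped)
        ph = phase_trios(ts)
        res = scan_windows(ph, sizes=(2,), min_het_dams=0, min_informative=0,
                           freq_floor=0.0, null_reps=0)
        assert {r.pseudo_allele for r in res} == {"AB", "BA", "AA"}

    def test_recoding_conserves_informative_totals(self, mixed_sim):
        cfg, ts, truth = mixed_sim
        ph = phase_trios(ts, labels=list(truth.labels))
        res = scan_windows(ph, sizes=(4,), min_het_dams=0, min_informative=1,
                           freq_floor=0.0, null_reps=0)
        for r in res:
            c = r.counts
            assert c.n_a_dam + c.n_b_dam == c.n_informative

    def test_perfect_ld_window_matches_single_snp(self):
        """A 2-SNP window of duplicated markers reproduces the single-SNP
        dam counts through the haplotype route."""
        cfg = SimConfig(n_sires=40, n_trios=800, n_het_markers=1,
                        n_par_markers=0, seed=31)
        ts, _ = simulate(cfg)
        gt = ts.genotypes
        calls = np.vstack([gt.calls, gt.calls])  # duplicate the marker
        gt2 = GenotypeTable(ids=gt.ids, sex=gt.sex, calls=calls,
                            markers=make_markers(2))
        ped = list(zip(ts.offspring_id, ts.sire_id, ts.dam_id, ts.off_sex))
        ts2 = assemble_trios(gt2, ped)
        single = dam_transmissions_heterosomal(ts2, 0)
        ph = phase_trios(ts2)
        res = scan_windows(ph, sizes=(2,), min_het_dams=0, min_informative=1,
                           freq_floor=0.0, null_reps=0)
        by_allele = {r.pseudo_allele: r.counts for r in res}
        assert by_allele["AA"].n_a_dam == single.n_a_dam
        assert by_allele["AA"].n_b_dam == single.n_b_dam

    @pytest.mark.parametrize("n_dams_het,kept", [(9, False), (10, True)])
    def test_het_dam_floor(self, n_dams_het, kept):
        """Windows below the heterozygous-dam floor are discarded."""
        n_trios = 60
        n_het = n_dams_het
        sire = np.zeros((2, n_trios), dtype=np.int8)
        dam = np.zeros((2, n_trios), dtype=np.int8)
        dam[:, :n_het] = 1
        off = np.zeros((2, n_trios), dtype=np.int8)
        calls = np.zeros((2, 3 * n_trios), dtype=np.int8)
        calls[:, :n_trios] = sire
        calls[:, n_trios:2 * n_trios] = dam
        calls[:, 2 * n_trios:] = off
        sexes = ["male"] * n_trios + ["female"] * n_trios + ["male"] * n_trios
        ped = [(f"i{2 * n_trios + k}", f"i{k}", f"i{n_trios + k}", "male")
               for k in range(n_trios)]
        ts = make_trioset(calls, sexes, ped)
        ph = phase_trios(ts)
        res = scan_windows(ph, sizes=(2,), min_het_dams=10, min_informative=1,
                           freq_floor=0.0, null_reps=0)
        assert bool(res) == kept

    def test_window_spanning_boundary_skipped(self, mixed_sim):
        cfg, ts, truth = mixed_sim
        ph = phase_trios(ts, labels=list(truth.labels))
        res = scan_windows(ph, sizes=(4,), min_het_dams=0, min_informative=1,
                           freq_floor=0.0, null_reps=0)
        starts = {r.marker_index for r in res}
        crossing = set(range(cfg.n_het_markers - 3, cfg.n_het_markers))
        assert starts.isdisjoint(crossing)


def test_window_catalog_frequencies_sum_to_one(mixed_sim):
    from xtrd.windows import window_catalog

    cfg, ts, truth = mixed_sim
    ph = phase_trios(ts, labels=list(truth.labels))
    w = window_catalog(ph, 0, 4)
    assert w.start_bp == ts.markers.pos[0]
    assert sum(w.catalog.values()) == pytest.approx(1.0)
    assert all(len(h) == 4 for h in w.catalog)


class TestScanAndConsolidate:
    def test_injected_haplotype_distortion_detected(self):
        """A 4-SNP haplotype transmitted at 0.25 from carrier dams reaches
        decisive evidence with alpha within 0.05 of -0.25."""
        hap = (0, 1, 1, 0)
        cfg = SimConfig(n_sires=100, n_trios=5000, n_het_markers=12,
                        n_par_markers=0,
                        dam_hap_trd=(((4, 5, 6, 7), hap, -0.25),), seed=7)
        ts, _ = simulate(cfg)
        ph = phase_trios(ts)
        res = scan_windows(ph, sizes=(4,), null_reps=0)
        r = next(r for r in res
                 if r.marker_index == 4 and r.pseudo_allele == "ABBA")
        assert r.log10_bf["alpha_d"] >= 2.0
        assert r.mean("alpha_d") == pytest.approx(-0.25, abs=0.05)

    def test_isolated_window_is_own_region(self):
        from xtrd.inference import TrdResult

        r = TrdResult(id="w", params={"alpha_d": (-0.3, 0.01)},
                      log10_bf={"alpha_d": 8.0}, random_trd_class="<=0.001%",
                      marker_index=5, window_size=4)
        regions = consolidate([r])
        assert len(regions) == 1
        assert regions[0].representative is r

    def test_overlapping_windows_merge(self):
        from xtrd.inference import TrdResult

        rs = [
            TrdResult(id=f"w{k}", params={"alpha_d": (-0.3, 0.01)},
                      log10_bf={"alpha_d": 8.0 - k},
                      random_trd_class="<=0.001%",
                      marker_index=5 + k, window_size=4)
            for k in range(2)
        ]
        regions = consolidate(rs)
        assert len(regions) == 1
        assert len(regions[0].members) == 2

    def test_spaced_signals_stay_separate(self):
        cfg = SimConfig(
            n_sires=100, n_trios=4000, n_het_markers=30, n_par_markers=0,
            dam_trd={5: {"pooled": -0.3}, 15: {"pooled": 0.3},
                     25: {"pooled": -0.3}},
            seed=13,
        )
        ts, _ = simulate(cfg)
        ph = phase_trios(ts)
        res = scan_windows(ph, sizes=(2,), null_reps=200_000)
        regions = consolidate(res, max_class="<=0.001%")
        assert len(regions) == 3
        reps = sorted(r.representative.marker_index for r in regions)
        for rep, signal in zip(reps, (5, 15, 25)):
            assert abs(rep - signal) <= 2

    def test_empty_input_empty_output(self):
        assert consolidate([]) == []
        cfg = SimConfig(n_sires=5, n_trios=20, n_het_markers=0,
                        n_par_markers=4, seed=1)
        ts, truth = simulate(cfg)
        ph = phase_trios(ts, labels=list(truth.labels))
        assert recessive_scan(ph, sizes=(2,), config=SHORT_CHAIN) == []


class TestRecessiveScan:
    def test_lethal_haplotype_detected(self):
        cfg = SimConfig(n_sires=100, n_trios=3000, n_het_markers=6,
                        n_par_markers=0, lethal_markers=(2, 3),
                        lethal_haplotype=(1, 1), sex_ratio=0.3, seed=8)
        ts, _ = simulate(cfg)
        ph = phase_trios(ts)
        res = recessive_scan(ph, sizes=(2,), config=SHORT_CHAIN)
        r = next(r for r in res
                 if r.marker_index == 2 and r.pseudo_allele == "BB")
        assert r.mean("alpha_g") < 0
        assert r.mean("delta_g") > 0
        assert r.log10_bf["alpha_g"] >= 2.0
        carrier = r.table.classes[("A", "AB")]
        assert carrier[0] == 0  # no surviving homozygotes
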