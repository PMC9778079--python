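"""Bayesian TRD estimation: closed form, sampler, Bayes factors, null."""

import math

import numpy as np
import pytest
from scipy import stats

from xtrd import (
    TransmissionCounts, TrdModelSpec, McmcConfig, AllelicTrdModel,
    GenotypicTrdModel, fit_allelic, fit_genotypic,
    beta_posterior_mean, bayes_factor_binomial,
    NullDistribution, empirical_null,
)
from xtrd.transmissions import MatingGenotypeTable
from xtrd.inference import _mendelian_offspring


def mcse(x, n_batches=20):
    """Batch-means Monte-Carlo standard error of a chain mean."""
    x = np.asarray(x)
    k = len(x) // n_batches
    means = x[: k * n_batches].reshape(n_batches, k).mean(axis=1)
    return means.std(ddof=1) / math.sqrt(n_batches)


# ---------------------------------------------------------------------------
# closed form

#: printed worked examples: (n_A, n_B, posterior mean to 2 dp, log10 BF, BF dp)
WORKED = [
    (470, 757, -0.12, 13.3, 1),
    (0, 72, -0.49, 19.81, 2),
    (5, 91, -0.44, 19.13, 2),
    (118, 310, -0.22, 18.12, 2),
    (13, 103, -0.38, 16.11, 2),
    (964, 623, 0.11, 14.5, 1),
    (912, 707, 0.06, 4.14, 2),
]


@pytest.mark.parametrize("n_a,n_b,mean,bf,dp", WORKED)
def test_closed_form_reproduces_printed_estimates(n_a, n_b, mean, bf, dp):
    assert round(beta_posterior_mean(n_a, n_b), 2) == mean
    assert abs(bayes_factor_binomial(n_a, n_b) - bf) <= 0.5 * 10 ** (-dp) + 1e-9


def test_balanced_counts_give_zero_alpha_and_null_support():
    assert beta_posterior_mean(60, 60) == 0.0
    # evidence favors the null for balanced counts
    assert bayes_factor_binomial(50, 50) == pytest.approx(-0.90, abs=0.01)


def test_no_data_gives_unit_bayes_factor_and_flag():
    assert bayes_factor_binomial(0, 0) == 0.0
    r = fit_allelic(TransmissionCounts())
    assert r.params == {}
    assert any("no informative" in f for f in r.flags)


def test_monotonicity_in_imbalance():
    """For fixed n, |alpha_hat| and the BF grow with the count imbalance."""
    n = 300
    means = [abs(beta_posterior_mean(n // 2 - k, n // 2 + k))
             for k in range(0, 120, 10)]
    bfs = [bayes_factor_binomial(n // 2 - k, n // 2 + k)
           for k in range(0, 120, 10)]
    assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
    assert all(b >= a - 1e-12 for a, b in zip(bfs, bfs[1:]))


# ---------------------------------------------------------------------------
# sampler vs analytics


CHAIN = McmcConfig(iterations=24_000, burn_in=4_000, seed=9)


def test_sampler_matches_beta_analytics_on_random_counts():
    """50 random binomial-reducible count sets: posterior mean within
    3 Monte-Carlo SE of the Beta mean, BF within 0.1 log10 units."""
    rng = np.random.default_rng(12345)
    spec = TrdModelSpec()
    for _ in range(50):
        n = int(rng.integers(5, 2000))
        n_a = int(rng.binomial(n, rng.uniform(0.05, 0.95)))
        counts = TransmissionCounts(n_a_dam=n_a, n_b_dam=n - n_a,
                                    n_informative=n)
        m = AllelicTrdModel(spec=spec, config=CHAIN, method="mcmc").fit(counts)
        exact_mean = beta_posterior_mean(n_a, n - n_a)
        se = max(mcse(m.samples_[:, 0]), 1e-6)
        assert abs(m.posterior_mean_["alpha_d"] - exact_mean) <= 3 * se
        assert abs(m.log10_bf_["alpha_d"]
                   - bayes_factor_binomial(n_a, n - n_a)) <= 0.1


def test_sampler_handles_boundary_posterior():
    counts = TransmissionCounts(n_a_dam=0, n_b_dam=72, n_informative=72)
    m = AllelicTrdModel(config=CHAIN, method="mcmc").fit(counts)
    assert m.posterior_mean_["alpha_d"] == pytest.approx(
        beta_posterior_mean(0, 72), abs=0.01)
    assert m.log10_bf_["alpha_d"] == pytest.approx(
        bayes_factor_binomial(0, 72), abs=0.1)


def test_joint_sire_dam_model_with_ambiguous_class():
    """AB x AB -> AB offspring enter as a mixture; with symmetric data the
    posterior stays near zero for both parents."""
    counts = TransmissionCounts(
        n_a_dam=250, n_b_dam=250, n_a_sire=250, n_b_sire=250,
        n_ambiguous=300, n_informative=1300,
    )
    spec = TrdModelSpec(region="pseudoautosomal", parents=("sire", "dam"))
    m = AllelicTrdModel(spec=spec, config=CHAIN, method="mcmc").fit(counts)
    for name in ("alpha_s", "alpha_d"):
        assert abs(m.posterior_mean_[name]) < 0.05
        assert m.log10_bf_[name] < 1.0


def test_heterosomal_spec_rejects_sire_parameters():
    with pytest.raises(ValueError, match="dam"):
        TrdModelSpec(region="heterosomal", parents=("sire", "dam"))


# ---------------------------------------------------------------------------
# genotypic model


def grid_posterior_mean(table, n=301):
    """Independent 2-D quadrature oracle over (alpha_g, delta_g)."""
    ag = np.linspace(-0.999, 0.999, n)
    dg = np.linspace(-0.999, 0.999, n)
    AG, DG = np.meshgrid(ag, dg, indexing="ij")
    ll = np.zeros_like(AG)
    for key, cnt in table.classes.items():
        mend = _mendelian_offspring(key)
        W = np.stack([1 + AG, 1 + DG, 1 - AG])
        probs = mend[:, None, None] * W
        tot = probs.sum(0)
        for c, pr in zip(cnt, probs):
            if c > 0:
                ll += c * (np.log(pr) - np.log(tot))
    ll -= ll.max()
    w = np.exp(ll)
    w /= w.sum()
    return float((AG * w).sum()), float((DG * w).sum())


def test_genotypic_posterior_matches_grid_oracle():
    rng = np.random.default_rng(21)
    for _ in range(5):
        t = MatingGenotypeTable()
        t.classes[("A", "AB")] = np.append(rng.integers(0, 20, 2), 0)
        t.classes[("B", "AB")] = np.insert(rng.integers(0, 20, 2), 0, 0)
        m = GenotypicTrdModel(config=CHAIN).fit(t)
        g_ag, g_dg = grid_posterior_mean(t)
        assert abs(m.posterior_mean_["alpha_g"] - g_ag) <= \
            3 * max(mcse(m.samples_[:, 0]), 1e-4)
        assert abs(m.posterior_mean_["delta_g"] - g_dg) <= \
            3 * max(mcse(m.samples_[:, 1]), 1e-4)


def test_mendelian_proportions_give_null_genotypic_fit():
    t = MatingGenotypeTable()
    t.classes[("A", "AB")] = np.array([400, 400, 0])
    t.classes[("B", "AB")] = np.array([0, 400, 400])
    r = fit_genotypic(t, config=CHAIN)
    assert abs(r.mean("alpha_g")) < 0.05
    assert abs(r.mean("delta_g")) < 0.05
    assert r.log10_bf["alpha_g"] < 1.0


def test_missing_homozygotes_give_recessive_signature():
    t = MatingGenotypeTable()
    t.classes[("A", "AB")] = np.array([0, 80, 0])   # no AA observed
    t.classes[("B", "AB")] = np.array([0, 500, 500])
    r = fit_genotypic(t, config=CHAIN)
    assert r.mean("alpha_g") < 0
    assert r.mean("delta_g") > 0
    assert r.log10_bf["alpha_g"] >= 2.0


def test_modeled_probabilities_normalize():
    rng = np.random.default_rng(8)
    for _ in range(50):
        ag, dg = rng.uniform(-0.99, 0.99, 2)
        w = np.array([1 + ag, 1 + dg, 1 - ag])
        for key in (("A", "AB"), ("B", "AB"), ("AB", "AB")):
            mend = _mendelian_offspring(key)
            probs = mend * w
            assert probs.sum() > 0
            probs /= probs.sum()
            assert probs.sum() == pytest.approx(1.0)
            assert np.all(probs >= 0)


# ---------------------------------------------------------------------------
# empirical null


def test_empirical_null_matches_exact_binomial_tail():
    null = NullDistribution(72, n_reps=400_000, seed=4)
    # oracle: P(|alpha_hat| >= obs) under Binomial(72, 1/2) exactly
    obs = abs(beta_posterior_mean(20, 52))
    k = np.arange(73)
    a = np.abs((k + 1) / 74 - 0.5)
    exact = stats.binom.pmf(k[a >= obs - 1e-12], 72, 0.5).sum()
    three_sigma = 3 * math.sqrt(exact * (1 - exact) / null.n_reps)
    assert null.tail_prob(obs) == pytest.approx(exact, abs=three_sigma + 1e-5)


def test_extreme_observation_reaches_finest_class():
    null = NullDistribution(72, n_reps=1_000_000, seed=4)
    # 0 of 72: exact tail 2 * 0.5**72 is far below 1e-5
    assert null.classify(beta_posterior_mean(0, 72)) == "<=0.001%"


def test_null_observation_is_unclassified():
    null = NullDistribution(500, n_reps=100_000, seed=1)
    assert null.classify(0.0) == ">5%"


def test_zero_informative_rejected():
    with pytest.raises(ValueError, match="undefined"):
        NullDistribution(0)


def test_cache_reuses_distributions():
    a = empirical_null(137, n_reps=10_000, seed=3)
    b = empirical_null(137, n_reps=10_000, seed=3)
    assert a is b


def test_type_one_error_control_under_mendelian_null():
    """Under alpha = 0, markers reaching both BF >= 100 and class <=0.1%
    stay at or below the nominal class level."""
    rng = np.random.default_rng(99)
    n, reps = 500, 2000
    null = empirical_null(n, n_reps=200_000, seed=11)
    hits = 0
    for _ in range(reps):
        n_a = rng.binomial(n, 0.5)
        ahat = beta_posterior_mean(n_a, n - n_a)
        if bayes_factor_binomial(n_a, n - n_a) >= 2.0:
            cls = null.classify(ahat)
            if cls in ("<=0.001%", "<=0.01%", "<=0.1%"):
                hits += 1
    # nominal 0.1% plus 3 binomial sigma
    bound = 0.001 + 3 * math.sqrt(0.001 * 0.999 / reps)
    assert hits / reps <= bound


# ---------------------------------------------------------------------------
# parameter recovery (reduced; the acceptance suite runs the full design)


@pytest.mark.parametrize("alpha", [-0.3, -0.1, 0.0, 0.1, 0.3])
def test_injected_alpha_recovered(alpha):
    rng = np.random.default_rng(abs(hash(alpha)) % 2**31)
    n = 2000
    ok = 0
    reps = 30
    for _ in range(reps):
        n_a = rng.binomial(n, 0.5 + alpha)
        counts = TransmissionCounts(n_a_dam=n_a, n_b_dam=n - n_a,
                                    n_informative=n)
        r = fit_allelic(counts)
        ok += abs(r.mean("alpha_d") - alpha) <= 0.03
    assert ok >= math.ceil(0.9 * reps)
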