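"""Bayesian TRD estimation and testing.

Allelic model
    Each resolved transmission from a heterozygous parent is Bernoulli with
    P(A) = 0.5 + alpha, where alpha in (-0.5, 0.5) is the TRD parameter of
    that parent (sire/dam) and offspring-sex stratum.  Ambiguous
    AB x AB -> AB offspring contribute the mixture term
    P_s(A) P_d(B) + P_s(B) P_d(A).  Priors are uniform over (-0.5, 0.5).
    When the model reduces to a single binomial the posterior of
    p = 0.5 + alpha is Beta(n_A + 1, n_B + 1) in closed form.

Genotypic model
    Offspring-genotype probabilities per mating class are Mendelian
    expectations reweighted by genotype factors 1 + alpha_g (AA),
    1 + delta_g (AB) and 1 - alpha_g (BB), renormalized within the class;
    priors are uniform over (-1, 1).  The recessive-lethal signature is
    alpha_g < 0 compensated by delta_g > 0.

Testing
    Bayes factors use the Savage-Dickey density ratio at the null
    (alpha = 0): BF = prior density / posterior density at 0.  The
    sampler-based path estimates the posterior ordinate by Rao-Blackwell
    averaging of the conditional density over post-burn-in draws, which is
    exact for one-parameter models.  Decisive evidence is BF >= 100
    (log10 BF >= 2) on Jeffreys' scale.

Calibration
    The empirical null simulates transmissions under Mendelian segregation
    with the observed family structure and reports the upper-tail
    probability class of |alpha_hat| among
    {<=0.001%, <=0.01%, <=0.1%, <=1%, <=5%, >5%}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy import stats
from scipy.special import logsumexp

from .trio_data import MALE, FEMALE
from .transmissions import TransmissionCounts, MatingGenotypeTable, POOLED

LOG10 = math.log(10.0)

#: random-TRD probability classes (label, upper tail probability)
RANDOM_TRD_CLASSES = [
    ("<=0.001%", 1e-5),
    ("<=0.01%", 1e-4),
    ("<=0.1%", 1e-3),
    ("<=1%", 1e-2),
    ("<=5%", 5e-2),
]
CLASS_NONE = ">5%"


# ---------------------------------------------------------------------------
# specs and results


@dataclass
class TrdModelSpec:
    """Which allelic TRD parameters are active.

    ``parents`` is a subset of {"sire", "dam"} or ("overall",) for a single
    shared parameter; ``by_offspring_sex`` splits each parent parameter into
    male-/female-offspring components.  The heterosomal region admits only
    dam parameters.
    """

    region: str = "heterosomal"
    parents: tuple = ("dam",)
    by_offspring_sex: bool = False

    def __post_init__(self) -> None:
        allowed = {"sire", "dam", "overall"}
        if not set(self.parents) <= allowed:
            raise ValueError(f"parents must be in {allowed}")
        if "overall" in self.parents and len(self.parents) > 1:
            raise ValueError("'overall' excludes parent-specific parameters")
        if self.region == "heterosomal" and set(self.parents) - {"dam"}:
            raise ValueError("heterosomal region admits only dam-specific TRD")

    def param_name(self, parent: str, sex: str) -> str:
        base = {"sire": "alpha_s", "dam": "alpha_d", "overall": "alpha"}[parent]
        if not self.by_offspring_sex or sex == POOLED:
            return base
        return base + {MALE: "_m", FEMALE: "_f"}[sex]


@dataclass
class McmcConfig:
    """Single-chain random-walk Metropolis settings."""

    iterations: int = 110_000
    burn_in: int = 10_000
    seed: int = 20221209
    proposal_scale: float | None = None  # None: scaled from the data
    bf_subsample: int = 200  # draws used for the Rao-Blackwell BF ordinate

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")


@dataclass
class TrdResult:
    """Posterior summaries for one marker or haplotype window."""

    id: str
    params: dict = field(default_factory=dict)  # name -> (mean, sd)
    log10_bf: dict = field(default_factory=dict)
    random_trd_class: str | None = None
    counts: TransmissionCounts | None = None
    table: MatingGenotypeTable | None = None
    chrom: str | None = None
    start_bp: int | None = None
    end_bp: int | None = None
    region: str | None = None
    stratum: str | None = None
    window_size: int | None = None
    n_underrepresented: int | None = None
    flags: list = field(default_factory=list)
    marker_index: int | None = None
    pseudo_allele: str | None = None

    def mean(self, name: str) -> float:
        return self.params[name][0]

    def decisive(self, name: str) -> bool:
        return self.log10_bf.get(name, -np.inf) >= 2.0


# ---------------------------------------------------------------------------
# closed-form binomial path


def beta_posterior_mean(n_a: int, n_b: int) -> float:
    """Posterior mean of alpha = p - 0.5 under a uniform prior."""
    return (n_a + 1) / (n_a + n_b + 2) - 0.5


def beta_posterior_sd(n_a: int, n_b: int) -> float:
    a, b = n_a + 1, n_b + 1
    return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


def bayes_factor_binomial(n_a: int, n_b: int) -> float:
    """log10 Savage-Dickey Bayes factor for alpha = 0 vs free alpha.

    With a uniform prior over (-0.5, 0.5) the prior ordinate at 0 is 1, so
    BF = 1 / BetaPDF(0.5; n_A + 1, n_B + 1).  No data gives BF = 1.
    """
    if n_a == 0 and n_b == 0:
        return 0.0
    return float(-stats.beta.logpdf(0.5, n_a + 1, n_b + 1) / LOG10)


# ---------------------------------------------------------------------------
# generic random-walk Metropolis-within-Gibbs


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    # guard against landing exactly on a bound
    eps = 1e-12 * width
    return min(max(x, lo + eps), hi - eps)


def _run_chain(loglik, x0, lo, hi, scales, cfg: McmcConfig, rng):
    """One chain with per-parameter reflecting random-walk updates.

    Proposal scales adapt toward ~40% acceptance during burn-in only.
    Returns post-burn-in samples, shape (iterations - burn_in, P).
    """
    x = np.array(x0, dtype=float)
    p = len(x)
    scales = np.array(scales, dtype=float)
    cur = loglik(x)
    keep = np.empty((cfg.iterations - cfg.burn_in, p))
    acc = np.zeros(p)
    window = np.zeros(p)
    for it in range(cfg.iterations):
        for j in range(p):
            prop = x.copy()
            prop[j] = _reflect(x[j] + rng.normal(0.0, scales[j]), lo[j], hi[j])
            new = loglik(prop)
            if new - cur > math.log(rng.random() + 1e-300):
                x = prop
                cur = new
                acc[j] += 1
            window[j] += 1
        if it < cfg.burn_in and (it + 1) % 200 == 0:
            rate = acc / window
            scales *= np.exp(1.2 * (rate - 0.40))
            scales = np.clip(scales, 1e-5, (hi - lo) / 2)
            acc[:] = 0
            window[:] = 0
        if it >= cfg.burn_in:
            keep[it - cfg.burn_in] = x
    return keep


def _rao_blackwell_log_ordinate(loglik_vec, samples, j, lo, hi, n_grid=2001,
                                n_sub=200):
    """log posterior density of parameter j at 0, averaged over draws.

    For each retained draw, the conditional density of parameter j given the
    others is evaluated on a grid by quadrature; the marginal ordinate is the
    average of the conditional ordinates (exact when P = 1).
    ``loglik_vec`` evaluates a (k, P) matrix of points to a length-k vector.
    """
    grid = np.linspace(lo + 1e-9, hi - 1e-9, n_grid)
    if 0.0 not in grid:
        grid = np.sort(np.append(grid, 0.0))
    i0 = int(np.searchsorted(grid, 0.0))
    idx = np.linspace(0, len(samples) - 1, min(n_sub, len(samples))).astype(int)
    log_ords = []
    for t in idx:
        pts = np.tile(samples[t], (len(grid), 1))
        pts[:, j] = grid
        ll = loglik_vec(pts)
        logz = _log_trapz(ll, grid)
        log_ords.append(ll[i0] - logz)
    return float(logsumexp(log_ords) - math.log(len(log_ords)))


def _log_trapz(log_f: np.ndarray, x: np.ndarray) -> float:
    dx = np.diff(x)
    pair = np.logaddexp(log_f[:-1], log_f[1:]) + np.log(dx / 2)
    return float(logsumexp(pair))


# ---------------------------------------------------------------------------
# allelic model


class AllelicTrdModel:
    """Allelic TRD fit with a fit()-style API.

    Parameters
    ----------
    spec : TrdModelSpec
        Active parameters and region.
    config : McmcConfig, optional
        Chain settings; defaults to 110,000 iterations / 10,000 burn-in.
    method : {"auto", "exact", "mcmc"}
        "exact" uses the closed-form Beta posterior (available when every
        parameter reduces to a single binomial and there is no ambiguous
        class); "auto" picks it whenever available.

    Fitted attributes: ``posterior_mean_``, ``posterior_sd_``, ``log10_bf_``
    (dicts keyed by parameter name), ``samples_`` (MCMC path only),
    ``result_``.
    """

    def __init__(self, spec: TrdModelSpec | None = None,
                 config: McmcConfig | None = None, method: str = "auto"):
        self.spec = spec or TrdModelSpec()
        self.config = config or McmcConfig()
        if method not in ("auto", "exact", "mcmc"):
            raise ValueError("method must be auto/exact/mcmc")
        self.method = method

    # -- model structure ----------------------------------------------------

    def _cells(self, counts_list):
        """(param, n_a, n_b) binomial cells + ambiguous mixture cells."""
        cells = []
        amb = []  # (n_amb, sire_param_or_None, dam_param_or_None)
        for c in counts_list:
            sex = c.stratum
            for parent in self.spec.parents:
                if parent == "overall":
                    name = self.spec.param_name("overall", sex)
                    na = c.n_a_dam + c.n_a_sire
                    nb = c.n_b_dam + c.n_b_sire
                elif parent == "dam":
                    name = self.spec.param_name("dam", sex)
                    na, nb = c.n_a_dam, c.n_b_dam
                else:
                    name = self.spec.param_name("sire", sex)
                    na, nb = c.n_a_sire, c.n_b_sire
                cells.append((name, na, nb))
            if c.n_ambiguous:
                sp = dp = None
                if "overall" in self.spec.parents:
                    sp = dp = self.spec.param_name("overall", sex)
                else:
                    if "sire" in self.spec.parents:
                        sp = self.spec.param_name("sire", sex)
                    if "dam" in self.spec.parents:
                        dp = self.spec.param_name("dam", sex)
                # with one free parent the mixture term is constant 1/2
                if sp is not None and dp is not None:
                    amb.append((c.n_ambiguous, sp, dp))
        return cells, amb

    def fit(self, counts) -> "AllelicTrdModel":
        if isinstance(counts, TransmissionCounts):
            counts = [counts]
        self.counts_ = list(counts)
        cells, amb = self._cells(self.counts_)

        names = []
        for name, _, _ in cells:
            if name not in names:
                names.append(name)
        per_param = {n: [0, 0] for n in names}
        for name, na, nb in cells:
            per_param[name][0] += na
            per_param[name][1] += nb
        flags = []
        active = []
        for n in names:
            has_amb = any(n in (sp, dp) for _, sp, dp in amb)
            if per_param[n][0] + per_param[n][1] == 0 and not has_amb:
                flags.append(f"no informative transmissions for {n}")
            else:
                active.append(n)
        self.flags_ = flags
        self.param_names_ = active
        if not active:
            self.posterior_mean_, self.posterior_sd_, self.log10_bf_ = {}, {}, {}
            self._finalize()
            return self

        exact_possible = not amb
        if self.method == "exact" and not exact_possible:
            raise ValueError("exact path needs a model without ambiguous cells")
        if self.method == "exact" or (self.method == "auto" and exact_possible):
            self.posterior_mean_ = {}
            self.posterior_sd_ = {}
            self.log10_bf_ = {}
            for n in active:
                na, nb = per_param[n]
                self.posterior_mean_[n] = beta_posterior_mean(na, nb)
                self.posterior_sd_[n] = beta_posterior_sd(na, nb)
                self.log10_bf_[n] = bayes_factor_binomial(na, nb)
            self.samples_ = None
            self.method_used_ = "exact"
        else:
            self._fit_mcmc(cells, amb, per_param)
            self.method_used_ = "mcmc"
        self._finalize()
        return self

    def _loglik_fn(self, cells, amb, names):
        pos = {n: i for i, n in enumerate(names)}
        bincells = [(pos[n], na, nb) for n, na, nb in cells
                    if n in pos and (na or nb)]
        ambcells = [
            (k, pos.get(sp), pos.get(dp)) for k, sp, dp in amb
        ]

        def loglik(x):
            ll = 0.0
            for j, na, nb in bincells:
                pa = 0.5 + x[j]
                ll += na * math.log(pa) + nb * math.log(1.0 - pa)
            for k, js, jd in ambcells:
                ps = 0.5 + (x[js] if js is not None else 0.0)
                pd = 0.5 + (x[jd] if jd is not None else 0.0)
                ll += k * math.log(ps * (1 - pd) + (1 - ps) * pd)
            return ll

        def loglik_vec(pts):
            ll = np.zeros(len(pts))
            for j, na, nb in bincells:
                pa = 0.5 + pts[:, j]
                ll += na * np.log(pa) + nb * np.log(1.0 - pa)
            for k, js, jd in ambcells:
                ps = 0.5 + (pts[:, js] if js is not None else 0.0)
                pd = 0.5 + (pts[:, jd] if jd is not None else 0.0)
                ll += k * np.log(ps * (1 - pd) + (1 - ps) * pd)
            return ll

        return loglik, loglik_vec

    def _fit_mcmc(self, cells, amb, per_param):
        names = self.param_names_
        p = len(names)
        loglik, loglik_vec = self._loglik_fn(cells, amb, names)
        rng = default_rng(self.config.seed)
        lo = np.full(p, -0.5)
        hi = np.full(p, 0.5)
        if self.config.proposal_scale is not None:
            scales = np.full(p, self.config.proposal_scale)
        else:
            scales = np.empty(p)
            for i, n in enumerate(names):
                na, nb = per_param[n]
                ntot = na + nb + 2
                scales[i] = max(2.4 * math.sqrt(0.25 / ntot), 1e-4)
        x0 = np.zeros(p)
        samples = _run_chain(loglik, x0, lo, hi, scales, self.config, rng)
        self.samples_ = samples
        self.posterior_mean_ = {n: float(samples[:, i].mean())
                                for i, n in enumerate(names)}
        self.posterior_sd_ = {n: float(samples[:, i].std(ddof=1))
                              for i, n in enumerate(names)}
        self.log10_bf_ = {}
        for i, n in enumerate(names):
            log_post0 = _rao_blackwell_log_ordinate(
                loglik_vec, samples, i, -0.5, 0.5,
                n_sub=self.config.bf_subsample,
            )
            # uniform prior over width 1: prior ordinate = 1
            self.log10_bf_[n] = float(-log_post0 / LOG10)

    def _finalize(self):
        n_under = 0
        for c in self.counts_:
            for parent in self.spec.parents:
                name = self.spec.param_name(
                    "overall" if parent == "overall" else parent, c.stratum
                )
                if name not in self.posterior_mean_:
                    continue
                if parent == "dam":
                    na, nb = c.n_a_dam, c.n_b_dam
                elif parent == "sire":
                    na, nb = c.n_a_sire, c.n_b_sire
                else:
                    na = c.n_a_dam + c.n_a_sire
                    nb = c.n_b_dam + c.n_b_sire
                n_under += na if self.posterior_mean_[name] < 0 else nb
        self.n_underrepresented_ = int(n_under)

    def result(self, id: str = "", **meta) -> TrdResult:
        return TrdResult(
            id=id,
            params={n: (self.posterior_mean_[n], self.posterior_sd_[n])
                    for n in self.posterior_mean_},
            log10_bf=dict(self.log10_bf_),
            counts=self.counts_[0] if len(self.counts_) == 1 else None,
            n_underrepresented=self.n_underrepresented_,
            flags=list(self.flags_),
            region=self.spec.region,
            **meta,
        )


def fit_allelic(counts, spec: TrdModelSpec | None = None,
                config: McmcConfig | None = None, method: str = "auto",
                id: str = "", **meta) -> TrdResult:
    """Fit the allelic TRD model and return a :class:`TrdResult`."""
    model = AllelicTrdModel(spec=spec, config=config, method=method).fit(counts)
    return model.result(id=id, **meta)


# ---------------------------------------------------------------------------
# genotypic model


def _mendelian_vector(parent_class: str) -> np.ndarray:
    """Allele-transmission distribution (P(A), P(B)) of a parent class."""
    if parent_class in ("A", "AA"):
        return np.array([1.0, 0.0])
    if parent_class in ("B", "BB"):
        return np.array([0.0, 1.0])
    if parent_class == "AB":
        return np.array([0.5, 0.5])
    raise ValueError(f"unknown parent class {parent_class!r}")


def _mendelian_offspring(key) -> np.ndarray:
    s = _mendelian_vector(key[0])
    d = _mendelian_vector(key[1])
    # offspring genotype (AA, AB, BB) from the two transmitted alleles
    return np.array(
        [s[0] * d[0], s[0] * d[1] + s[1] * d[0], s[1] * d[1]]
    )


class GenotypicTrdModel:
    """Genotypic (additive + dominance) TRD fit on a mating-genotype table.

    Genotype weights are 1 + alpha_g (AA), 1 + delta_g (AB), 1 - alpha_g
    (BB), renormalized within each mating class; uniform priors over (-1, 1).
    """

    PARAMS = ("alpha_g", "delta_g")

    def __init__(self, config: McmcConfig | None = None):
        self.config = config or McmcConfig()

    def _loglik_fn(self, table: MatingGenotypeTable):
        classes = [
            (tuple(float(c) for c in v), tuple(_mendelian_offspring(k)))
            for k, v in table.classes.items()
            if np.sum(v) > 0
        ]

        def loglik(x):
            ag, dg = x[0], x[1]
            w0, w1, w2 = 1.0 + ag, 1.0 + dg, 1.0 - ag
            ll = 0.0
            for (c0, c1, c2), (m0, m1, m2) in classes:
                p0, p1, p2 = m0 * w0, m1 * w1, m2 * w2
                tot = p0 + p1 + p2
                if c0 > 0:
                    if p0 <= 0:
                        return -np.inf
                    ll += c0 * math.log(p0 / tot)
                if c1 > 0:
                    if p1 <= 0:
                        return -np.inf
                    ll += c1 * math.log(p1 / tot)
                if c2 > 0:
                    if p2 <= 0:
                        return -np.inf
                    ll += c2 * math.log(p2 / tot)
            return ll

        def loglik_vec(pts):
            ag, dg = pts[:, 0], pts[:, 1]
            w = (1.0 + ag, 1.0 + dg, 1.0 - ag)
            ll = np.zeros(len(pts))
            with np.errstate(divide="ignore", invalid="ignore"):
                for cnt, mend in classes:
                    probs = [m * wi for m, wi in zip(mend, w)]
                    tot = probs[0] + probs[1] + probs[2]
                    for c, pr in zip(cnt, probs):
                        if c > 0:
                            ll += c * (np.log(pr) - np.log(tot))
            return np.where(np.isfinite(ll), ll, -np.inf)

        return loglik, loglik_vec

    def fit(self, table: MatingGenotypeTable) -> "GenotypicTrdModel":
        self.table_ = table
        loglik, loglik_vec = self._loglik_fn(table)
        rng = default_rng(self.config.seed)
        p = 2
        lo = np.full(p, -1.0)
        hi = np.full(p, 1.0)
        n = max(table.total(), 1)
        base = self.config.proposal_scale or max(2.4 / math.sqrt(n), 1e-3)
        samples = _run_chain(loglik, np.zeros(p), lo, hi,
                             np.full(p, base), self.config, rng)
        self.samples_ = samples
        self.posterior_mean_ = {n_: float(samples[:, i].mean())
                                for i, n_ in enumerate(self.PARAMS)}
        self.posterior_sd_ = {n_: float(samples[:, i].std(ddof=1))
                              for i, n_ in enumerate(self.PARAMS)}
        self.log10_bf_ = {}
        for i, n_ in enumerate(self.PARAMS):
            log_post0 = _rao_blackwell_log_ordinate(
                loglik_vec, samples, i, -1.0, 1.0,
                n_sub=self.config.bf_subsample,
            )
            # uniform prior over width 2: prior ordinate = 1/2
            self.log10_bf_[n_] = float((math.log(0.5) - log_post0) / LOG10)
        return self

    def result(self, id: str = "", **meta) -> TrdResult:
        tab = self.table_
        n_under = 0
        for key, v in tab.classes.items():
            mend = _mendelian_offspring(key)
            w = np.array([1.0 + self.posterior_mean_["alpha_g"],
                          1.0 + self.posterior_mean_["delta_g"],
                          1.0 - self.posterior_mean_["alpha_g"]])
            probs = mend * w
            probs = probs / probs.sum()
            under = (probs < mend / max(mend.sum(), 1e-300)) & (mend > 0)
            n_under += int(np.asarray(v)[under].sum())
        return TrdResult(
            id=id,
            params={n: (self.posterior_mean_[n], self.posterior_sd_[n])
                    for n in self.PARAMS},
            log10_bf=dict(self.log10_bf_),
            table=tab,
            n_underrepresented=n_under,
            **meta,
        )


def fit_genotypic(table: MatingGenotypeTable,
                  config: McmcConfig | None = None,
                  id: str = "", **meta) -> TrdResult:
    """Fit the genotypic TRD model and return a :class:`TrdResult`.

    Mating classes with zero total are skipped in the likelihood.
    """
    model = GenotypicTrdModel(config=config).fit(table)
    return model.result(id=id, **meta)


# ---------------------------------------------------------------------------
# empirical null


class NullDistribution:
    """Monte-Carlo null of |alpha_hat| under Mendelian transmission.

    Resolved transmissions are simulated as Binomial(n, 1/2) with the
    observed informative-offspring total; each replicate's posterior-mean
    alpha_hat uses the same closed-form estimator as the analysis.
    """

    def __init__(self, n_informative: int, n_reps: int = 1_000_000,
                 seed: int = 0):
        if n_informative <= 0:
            raise ValueError("empirical null undefined for n_informative = 0")
        self.n_informative = int(n_informative)
        self.n_reps = int(n_reps)
        rng = default_rng(seed)
        k = rng.binomial(self.n_informative, 0.5, size=self.n_reps)
        alpha = (k + 1) / (self.n_informative + 2) - 0.5
        self._abs_sorted = np.sort(np.abs(alpha))

    def tail_prob(self, alpha_hat: float) -> float:
        """P(|alpha_hat_null| >= |alpha_hat|), add-one adjusted."""
        i = np.searchsorted(self._abs_sorted, abs(alpha_hat) - 1e-12, side="left")
        exceed = self.n_reps - int(i)
        return (exceed + 1) / (self.n_reps + 1)

    def classify(self, alpha_hat: float) -> str:
        p = self.tail_prob(alpha_hat)
        for label, level in RANDOM_TRD_CLASSES:
            if p <= level:
                return label
        return CLASS_NONE


_NULL_CACHE: dict = {}


def empirical_null(n_informative: int, n_reps: int = 1_000_000,
                   seed: int = 0, bin_counts: bool = False) -> NullDistribution:
    """Cached empirical-null distribution for a given informative total.

    With ``bin_counts=True`` the total is rounded to two significant digits
    so that large scans reuse distributions across markers of similar size.
    """
    n = int(n_informative)
    if bin_counts and n > 100:
        mag = 10 ** (len(str(n)) - 2)
        n = (n // mag) * mag
    key = (n, n_reps, seed)
    if key not in _NULL_CACHE:
        _NULL_CACHE[key] = NullDistribution(n, n_reps=n_reps, seed=seed)
    return _NULL_CACHE[key]
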