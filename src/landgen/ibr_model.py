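"""Bayesian beta-binomial isolation-by-resistance model.

Allele-frequency differentiation among populations is modelled through a
parametric covariance on latent per-locus population frequencies:

    Omega[i,j] = (1/alpha0) * exp(-(alphaD*D[i,j] + sum_k alphaE_k*E_k[i,j])^alpha2)

for i != j, with Omega[i,i] = 1/alpha0.  D is standardized geographic
distance and each E_k a standardized landscape-resistance matrix (one
per census era).  Per locus l, latent frequencies are multivariate
normal with mean mu_l and covariance mu_l(1-mu_l)*Omega, truncated to
[0, 1]; observed alternate-allele counts are beta-binomial around the
latent frequency with a per-population dispersion phi_p.  The headline
statistic is the ratio alphaE/alphaD — the effect size of landscape
resistance relative to geographic distance.

Inference is Metropolis-within-Gibbs MCMC (kernel in
:mod:`landgen._mcmc`): random-walk updates of log alpha0, log alphaD,
log alphaE_k and log phi_p, single-site updates of the (scale
non-centered) latent frequencies, and independence proposals for mu_l
from a Beta centred on the pooled empirical frequency.  Priors:
exponential on the effect sizes alphaD and alphaE (rate 1 — the
covariates are SD-standardized, so rate 1 is weakly informative) and on
alpha0 (rate 0.01), log-flat on the dispersions, all within [1e-8,
1e8].  Proposal scales auto-tune during an initial discarded window
toward the target acceptance band (default 20-70%), then freeze.
alpha2 is fixed at 1 by default (estimable variants are a non-default
config concern and held fixed here).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .popgen import AlleleCountTable
from .resistance import PairwiseMatrix

logger = logging.getLogger(__name__)

LOG_BOUND = math.log(1e8)  # flat prior support on log parameters: [-LOG_BOUND, LOG_BOUND]


@dataclass
class IBRConfig:
    """MCMC run configuration (desk-scale defaults: 4 chains x 50,000 steps)."""

    n_steps: int = 50_000
    n_chains: int = 4
    thin: int = 10
    seed: int = 0
    covariate_labels: list[str] = field(default_factory=list)
    target_acceptance: tuple[float, float] = (0.20, 0.70)
    proposal_scales: dict = field(default_factory=dict)
    alpha2: float = 1.0
    tune_fraction: float = 0.2
    retain_fraction: float = 0.5
    subset_fraction: float = 1.0 / 32.0
    phi_period: int = 6
    alpha0_cycle: int = 3
    mu_concentration: float = 20.0
    infinity_factor: float = 10.0
    prior_rate_effect: float = 1.0   # exponential prior rate on alphaD, alphaE
    prior_rate_alpha0: float = 0.01  # exponential prior rate on alpha0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        lo, hi = self.target_acceptance
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("target_acceptance must be an interval inside (0, 1)")
        for k, v in self.proposal_scales.items():
            if v <= 0:
                raise ValueError(f"proposal scale {k!r} must be > 0")


@dataclass
class IBRPosterior:
    """One chain's thinned traces and diagnostics.

    Log-parameters are stored on the natural-log scale; ``ratio(k)``
    returns the alphaE_k/alphaD trace.
    """

    chain_id: int
    covariate_labels: list[str]
    log_alpha0: np.ndarray
    log_alphaD: np.ndarray
    log_alphaE: np.ndarray       # (n_rec, K)
    log_phi: np.ndarray          # (n_rec, P)
    log_posterior: np.ndarray
    acceptance_rates: dict[str, float]
    n_steps: int
    thin: int
    retain_fraction: float = 0.5

    @property
    def n_records(self) -> int:
        return len(self.log_alpha0)

    def retained(self) -> slice:
        """Record window used for final parameter estimates (second half)."""
        return slice(int(self.n_records * (1.0 - self.retain_fraction)), None)

    def ratio(self, k: int = 0) -> np.ndarray:
        return np.exp(self.log_alphaE[:, k] - self.log_alphaD)

    def ratio_estimate(self, k: int = 0) -> float:
        """Posterior median of alphaE_k/alphaD over the retained window.

        The ratio of two log-scale parameters is heavy-tailed; a few
        retained samples with alphaD near its prior floor can inflate a
        posterior mean by orders of magnitude, so the median is the
        chain's "final estimate".
        """
        return float(np.median(self.ratio(k)[self.retained()]))


@dataclass
class EffectSummary:
    """Per-covariate mean and SE of alphaE/alphaD across chains, plus HSD letters."""

    labels: list[str]
    mean_ratio: np.ndarray
    standard_error: np.ndarray
    hsd_group: list[str]
    per_chain: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "covariate": self.labels,
                "mean_ratio": self.mean_ratio,
                "standard_error": self.standard_error,
                "hsd_group": self.hsd_group,
            }
        )


# ---------------------------------------------------------------------------
# covariance and likelihood

def _as_values(mat) -> np.ndarray:
    return mat.values if isinstance(mat, PairwiseMatrix) else np.asarray(mat, float)


def build_covariance(
    D, E_list, alpha0: float, alphaD: float, alphaE, alpha2: float = 1.0
) -> np.ndarray:
    """Parametric allele-frequency covariance Omega (positive semidefinite).

    Adds diagonal jitter (logged) if the smallest eigenvalue falls below
    1e-10.
    """
    Dv = _as_values(D)
    if isinstance(D, PairwiseMatrix):
        for E in E_list:
            if isinstance(E, PairwiseMatrix) and E.site_ids != D.site_ids:
                raise ValueError("D and E matrices must share site ordering")
    Ev = [_as_values(E) for E in E_list]
    alphaE = np.atleast_1d(np.asarray(alphaE, float))
    if len(Ev) != len(alphaE):
        raise ValueError(f"{len(Ev)} resistance matrices but {len(alphaE)} alphaE values")
    if not (np.isfinite(Dv).all() and all(np.isfinite(E).all() for E in Ev)):
        raise ValueError("non-finite covariate entries; apply prepare_covariates first")
    if min(alpha0, alphaD, *alphaE, 1.0) < 0 or alpha0 <= 0:
        raise ValueError("alpha0 must be > 0 and effect sizes >= 0")
    S = alphaD * Dv
    for a, E in zip(alphaE, Ev):
        S = S + a * E
    with np.errstate(invalid="ignore"):
        omega = np.exp(-np.power(S, alpha2)) / alpha0
    np.fill_diagonal(omega, 1.0 / alpha0)
    omega = 0.5 * (omega + omega.T)
    w = np.linalg.eigvalsh(omega)
    if w.min() < 1e-10:
        jitter = max(1e-10 - w.min(), 1e-12)
        logger.info("build_covariance: adding %.3g diagonal jitter (min eig %.3g)", jitter, w.min())
        omega = omega + jitter * np.eye(omega.shape[0])
    return omega


def prepare_covariates(
    D: PairwiseMatrix, E_list: list[PairwiseMatrix], infinity_factor: float = 10.0
) -> tuple[PairwiseMatrix, list[PairwiseMatrix]]:
    """Make raw covariate matrices model-ready.

    Replaces +inf resistance entries by (max finite entry x factor) with
    a prominent warning, standardizes anything not yet standardized, and
    warns when a resistance matrix is nearly collinear with distance
    (|corr| > 0.99), which destabilizes the alphaE/alphaD ratio.
    """
    from .resistance import _standardize

    def fix(mat: PairwiseMatrix) -> PairwiseMatrix:
        vals = mat.values.copy()
        if np.isinf(vals).any():
            finite_max = vals[np.isfinite(vals)].max()
            repl = finite_max * infinity_factor
            logger.warning(
                "%s: replacing %d infinite entries with max finite x %g = %g",
                mat.label, int(np.isinf(vals).sum()), infinity_factor, repl,
            )
            vals[np.isinf(vals)] = repl
        std = mat.standardized
        if not std:
            vals = _standardize(vals, mat.label)
            std = True
        return PairwiseMatrix(mat.site_ids, vals, mat.label, standardized=std)

    Dp = fix(D)
    Ep = [fix(E) for E in E_list]
    d = Dp.upper_triangle()
    for E in Ep:
        r = np.corrcoef(d, E.upper_triangle())[0, 1]
        if abs(r) > 0.99:
            logger.warning(
                "%s is nearly collinear with geographic distance (|corr|=%.4f); "
                "the alphaE/alphaD ratio will be poorly identified", E.label, abs(r),
            )
    return Dp, Ep


def log_posterior(
    counts: AlleleCountTable,
    omega: np.ndarray,
    theta: np.ndarray,
    mu: np.ndarray,
    phi: np.ndarray,
    alphaD: float | None = None,
    alphaE=None,
    alpha0: float | None = None,
    prior_rate_effect: float = 1.0,
    prior_rate_alpha0: float = 0.01,
) -> float:
    """Joint log density at given latent frequencies (up to data constants).

    Sum over loci of the truncated-MVN latent prior plus the
    beta-binomial likelihood of the alternate-allele counts, with flat
    priors on the log-parameters.  Loci with no genotyped alleles in any
    population are excluded entirely.  Returns -inf (never NaN) for
    invalid states.
    """
    alt = np.asarray(counts.alt_count, float)
    m = np.asarray(counts.allele_number, float)
    keep = m.sum(axis=0) > 0
    alt, m = alt[:, keep], m[:, keep]
    theta = np.asarray(theta, float)[:, keep]
    mu = np.asarray(mu, float)[keep]
    phi = np.asarray(phi, float)
    P, L = theta.shape
    if (theta <= 0).any() or (theta >= 1).any() or (mu <= 0).any() or (mu >= 1).any():
        return -math.inf
    if (phi <= 0).any():
        return -math.inf

    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -math.inf
    oinv = np.linalg.inv(omega)
    x = theta - mu
    quad = np.einsum("pl,pq,ql->l", x, oinv, x)
    s = mu * (1.0 - mu)
    mvn = -0.5 * quad / s - 0.5 * (P * np.log(s) + logdet) - 0.5 * P * math.log(2 * math.pi)

    a = theta * phi[:, None]
    b = (1.0 - theta) * phi[:, None]
    with np.errstate(invalid="ignore"):
        bb = stats.betabinom.logpmf(alt, m, a, b)
    bb = np.where(m > 0, bb, 0.0)
    total = float(mvn.sum() + bb.sum())
    if alphaD is not None:
        total += math.log(prior_rate_effect) - prior_rate_effect * alphaD
    if alphaE is not None:
        for a in np.atleast_1d(alphaE):
            total += math.log(prior_rate_effect) - prior_rate_effect * float(a)
    if alpha0 is not None:
        total += math.log(prior_rate_alpha0) - prior_rate_alpha0 * alpha0
    return total if math.isfinite(total) else -math.inf


def marginal_loglik_single(
    alt: int, m: int, mu: float, sigma2: float, phi: float, n_nodes: int = 240
) -> float:
    """Single-population single-locus marginal log likelihood.

    Integrates the beta-binomial pmf of the count against the
    [0,1]-truncated normal latent prior by Gauss-Legendre quadrature —
    a validation utility for the observation layer (the sampler itself
    keeps latent frequencies explicit).
    """
    nodes, weights = leggauss(n_nodes)
    th = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    sd = math.sqrt(sigma2)
    zlo, zhi = (0.0 - mu) / sd, (1.0 - mu) / sd
    norm = stats.norm.cdf(zhi) - stats.norm.cdf(zlo)
    dens = stats.norm.pdf(th, loc=mu, scale=sd) / norm
    interior = (th > 0) & (th < 1)
    pmf = np.zeros_like(th)
    pmf[interior] = stats.betabinom.pmf(alt, m, th[interior] * phi, (1 - th[interior]) * phi)
    return float(np.log(np.sum(w * pmf * dens)))


# ---------------------------------------------------------------------------
# samplers

def metropolis_rw(logpdf, x0: float, scale: float, n_draws: int, seed: int, burn: int = 0):
    """Scalar random-walk Metropolis — the same accept rule the chain kernel
    applies to each parameter block.  Returns (draws, acceptance_rate)."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n_draws)
    acc = 0
    for i in range(burn + n_draws):
        xp = x + scale * rng.standard_normal()
        lpp = logpdf(xp)
        if math.log(rng.random()) < lpp - lp:
            x, lp = xp, lpp
            if i >= burn:
                acc += 1
        if i >= burn:
            out[i - burn] = x
    return out, acc / max(n_draws, 1)


def _chain_seed(base_seed: int, chain_id: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(chain_id)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _moment_init(kalt, m, Dv, Ev) -> tuple[float, np.ndarray]:
    """Method-of-moments starting values for (log alphaD, log alphaE).

    Pairwise correlations of empirical-frequency deviations from the
    pooled mean carry the covariates' imprint: to first order they fall
    linearly in alphaD*D + sum alphaE_k*E_k (the shared component and
    the sampling-noise nugget land in the intercept).  OLS of the
    correlation on [1, D, E_k] therefore points at which covariate the
    decay follows; the (sign-flipped, clipped) slopes are rescaled so
    the implied mean exponent is a moderate 0.5 and used as starting
    effect sizes.  Random-walk chains started blind instead tend to fall
    into a metastable no-landscape-effect mode and can spend most of a
    desk-scale run escaping it.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(m > 0, kalt / np.maximum(m, 1), np.nan)
    pooled = np.nansum(kalt, axis=0) / np.maximum(np.nansum(m, axis=0), 1)
    s = np.clip(pooled * (1 - pooled), 1e-4, None)
    x = (f - pooled[None, :]) / np.sqrt(s[None, :])
    x = np.where(np.isfinite(x), x, 0.0)
    C = np.corrcoef(x)
    iu = np.triu_indices(C.shape[0], k=1)
    design = np.column_stack(
        [np.ones(len(iu[0])), Dv[iu]] + [E[iu] for E in Ev]
    )
    coef, *_ = np.linalg.lstsq(design, C[iu], rcond=None)
    rel = np.maximum(-coef[1:], 0.0)
    means = np.array([Dv[iu].mean()] + [E[iu].mean() for E in Ev])
    total = float(rel @ means)
    scale = 0.5 / total if total > 0 else 0.0
    alphas = np.maximum(scale * rel, 0.02)
    # a too-flat exponent makes R a near-ones matrix (numerically
    # singular); scale the starting point up until R factorizes sanely
    for _ in range(30):
        S = alphas[0] * Dv
        for a, E in zip(alphas[1:], Ev):
            S = S + a * E
        R = np.exp(-S)
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() >= 1e-7:
            break
        alphas = alphas * 1.3
    return math.log(float(alphas[0])), np.log(alphas[1:])


_BLOCK_DEFAULTS = {"alpha": 0.5, "eps": 0.3, "phi": 0.4}


def run_chain(
    counts: AlleleCountTable,
    D: PairwiseMatrix,
    E_list: list[PairwiseMatrix],
    config: IBRConfig,
    chain_id: int = 0,
) -> IBRPosterior:
    """Run one MCMC chain; bit-identical under (seed, chain_id)."""
    from ._mcmc import run_chain_kernel

    Dp, Ep = prepare_covariates(D, E_list, config.infinity_factor)
    Dv = Dp.values
    Ev = np.stack([E.values for E in Ep])
    kalt = np.asarray(counts.alt_count, float)
    m = np.asarray(counts.allele_number, float)
    P, L = kalt.shape
    K = Ev.shape[0]
    if Dv.shape[0] != P:
        raise ValueError(f"counts have {P} populations but D is {Dv.shape[0]}x{Dv.shape[0]}")

    with np.errstate(invalid="ignore", divide="ignore"):
        emp = np.where(m > 0, kalt / np.maximum(m, 1), 0.5)
    pooled = kalt.sum(axis=0) / np.maximum(m.sum(axis=0), 1)
    pooled = np.clip(pooled, 0.02, 0.98)
    theta0 = np.clip(np.where(m > 0, emp, pooled[None, :]), 0.02, 0.98)
    mu0 = pooled.copy()

    scales = dict(_BLOCK_DEFAULTS)
    scales.update(config.proposal_scales)
    sig_glob = np.full(2 + 2 * K, float(scales["alpha"]))
    sig_eps = np.full(P, float(scales["eps"]))
    sig_phi = np.full(P, float(scales["phi"]))

    tune_end = int(config.n_steps * config.tune_fraction)
    subset = max(1, int(round(L * config.subset_fraction)))
    lo, hi = config.target_acceptance
    target_mid = 0.5 * (lo + hi) - 0.1  # aim slightly low in the band; RW optimum ~0.3

    la0_init = math.log(10.0)
    eps0 = (theta0 - mu0[None, :]) * math.exp(0.5 * la0_init)
    lad0, lae0 = _moment_init(kalt, m, Dv, Ev)
    lphi0 = np.full(P, math.log(50.0))
    trace, acc, prop = run_chain_kernel(
        kalt, m, Dv, Ev, float(config.alpha2), _chain_seed(config.seed, chain_id),
        int(config.n_steps), int(config.thin), tune_end, 500, target_mid,
        subset, int(config.phi_period), 2000,
        eps0, mu0, la0_init, lad0, lae0, lphi0,
        pooled, float(config.mu_concentration),
        sig_glob, sig_eps, sig_phi, np.array([0.08]), -LOG_BOUND, LOG_BOUND,
        float(config.prior_rate_alpha0), float(config.prior_rate_effect),
        int(config.alpha0_cycle),
    )

    labels = list(config.covariate_labels) or [f"E{k}" for k in range(K)]
    names = (
        ["alpha0", "alphaD"]
        + [f"alphaE:{lab}" for lab in labels[:K]]
        + [f"exchange:{lab}" for lab in labels[:K]]
        + [f"latent:{counts.populations[p]}" for p in range(P)]
        + [f"phi:{counts.populations[p]}" for p in range(P)]
        + ["mu", "mu_shift"]
    )
    with np.errstate(invalid="ignore"):
        rates = {n: float(a / p) if p > 0 else float("nan") for n, a, p in zip(names, acc, prop)}
    lo, hi = config.target_acceptance
    for n, r in rates.items():
        if not math.isnan(r) and not lo <= r <= hi:
            logger.warning(
                "chain %d: post-tuning acceptance rate for %s is %.3f "
                "(target %.0f-%.0f%%)", chain_id, n, r, lo * 100, hi * 100,
            )
    return IBRPosterior(
        chain_id=chain_id,
        covariate_labels=labels[:K],
        log_alpha0=trace[:, 0],
        log_alphaD=trace[:, 1],
        log_alphaE=trace[:, 2 : 2 + K],
        log_phi=trace[:, 2 + K : 2 + K + P],
        log_posterior=trace[:, 2 + K + P],
        acceptance_rates=rates,
        n_steps=config.n_steps,
        thin=config.thin,
        retain_fraction=config.retain_fraction,
    )


def run_chains(
    counts: AlleleCountTable,
    D: PairwiseMatrix,
    E_list: list[PairwiseMatrix],
    config: IBRConfig,
) -> list[IBRPosterior]:
    """Run ``config.n_chains`` independent chains (distinct RNG streams)."""
    return [run_chain(counts, D, E_list, config, chain_id=c) for c in range(config.n_chains)]


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(chains: list[np.ndarray], confidence: float = 0.95):
    """Potential scale reduction factor with its upper confidence bound.

    R-hat compares between-chain and within-chain variance; values near 1
    indicate that independent chains have mixed over the same
    distribution.  Returns (point estimate, upper bound); both are NaN
    (flagged via a warning) when the within-chain variance is zero.
    """
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    n = len(chains[0])
    if n < 10 or any(len(c) != n for c in chains):
        raise ValueError("chains must have equal length >= 10")
    mchains = len(chains)
    arr = np.asarray(chains, float)
    means = arr.mean(axis=1)
    variances = arr.var(axis=1, ddof=1)
    W = float(variances.mean())
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        logger.warning("gelman_rubin: zero within-chain variance; R-hat undefined")
        return float("nan"), float("nan")
    vhat = (n - 1) / n * W + B / n
    rhat = math.sqrt(vhat / W)
    # Brooks & Gelman upper bound: scale the between-chain term by an F quantile
    var_w = float(np.var(variances, ddof=1)) / mchains if mchains > 1 else 0.0
    df = 2 * W**2 / var_w if var_w > 0 else 1e6
    fq = stats.f.ppf(confidence + (1 - confidence) / 2, mchains - 1, df)
    upper = math.sqrt((n - 1) / n + (mchains + 1) / (mchains * n) * (B / W) * fq)
    return rhat, upper


def effect_summary(
    posteriors: list[IBRPosterior], era_labels: list[str], alpha: float = 0.05
) -> EffectSummary:
    """Mean and SE of per-chain alphaE/alphaD estimates per era, with HSD letters.

    Each chain contributes its posterior-mean ratio over the retained
    window; chains are grouped by covariate label and compared across
    eras by one-way ANOVA + Tukey HSD (letters shared by eras that do
    not differ significantly).
    """
    groups: dict[str, list[float]] = {str(lab): [] for lab in era_labels}
    for post in posteriors:
        for k, lab in enumerate(post.covariate_labels):
            if str(lab) in groups:
                groups[str(lab)].append(post.ratio_estimate(k))
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"era {lab!r} has {len(vals)} chain estimate(s); need >= 2 for an SE")
    arrs = {lab: np.asarray(v, float) for lab, v in groups.items()}
    mean = np.array([arrs[str(lab)].mean() for lab in era_labels])
    se = np.array(
        [arrs[str(lab)].std(ddof=1) / math.sqrt(len(arrs[str(lab)])) for lab in era_labels]
    )
    if len(era_labels) >= 2:
        from .association import anova_tukey

        hsd = anova_tukey({str(lab): arrs[str(lab)] for lab in era_labels}, alpha=alpha)
        letters = [hsd.letters[str(lab)] for lab in era_labels]
    else:
        letters = ["a"]
    return EffectSummary(
        labels=[str(lab) for lab in era_labels],
        mean_ratio=mean,
        standard_error=se,
        hsd_group=letters,
        per_chain=arrs,
    )
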