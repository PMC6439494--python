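"""Downstream statistical battery.

Residual regression of pairwise FST on landscape resistance after
geographic distance, one-way ANOVA with Tukey HSD (compact letter
display) for effect-size ratios across census eras, and the diversity
regressions.  Pairwise-matrix regressions use plain OLS on vectorized
upper triangles — pairs are not independent, so p-values are
anti-conservative; a Mantel-style permutation p-value is available
behind ``permutations=`` for the matrix regressions, off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .resistance import PairwiseMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Simple OLS fit summary (slope, intercept, R^2, slope p-value)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residuals: np.ndarray
    n: int
    permutation_p: float | None = None


@dataclass
class HSDResult:
    """One-way ANOVA + Tukey HSD with compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """

    group_means: dict[str, float]
    letters: dict[str, str]
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: list[tuple[str, str, float, bool]]  # (g1, g2, p_adj, reject)


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if len(y) < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        residuals=np.asarray(fit.resid),
        n=len(y),
    )


def _check_alignment(*mats: PairwiseMatrix) -> None:
    ids = mats[0].site_ids
    for m in mats[1:]:
        if m.site_ids != ids:
            raise ValueError(
                f"matrices {mats[0].label!r} and {m.label!r} have different site orderings"
            )


def residual_regression(
    fst: PairwiseMatrix,
    dist: PairwiseMatrix,
    resist: PairwiseMatrix,
    permutations: int = 0,
    seed: int = 0,
) -> tuple[RegressionResult, RegressionResult]:
    """FST ~ distance, then stage-1 residuals ~ resistance.

    Both stages are OLS on identically vectorized upper triangles;
    distance and resistance are expected SD-standardized (done by the
    resistance module before vectorizing).
    """
    _check_alignment(fst, dist, resist)
    y = fst.upper_triangle()
    d = dist.upper_triangle()
    e = resist.upper_triangle()
    stage1 = _ols(y, d)
    stage2 = _ols(stage1.residuals, e)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = fst.n
        obs = abs(stage2.slope)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            yp = fst.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
            r1 = _ols(yp, d)
            if abs(_ols(r1.residuals, e).slope) >= obs:
                count += 1
        stage2.permutation_p = (count + 1) / (permutations + 1)
    return stage1, stage2


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each group gets the letters of every maximal clique-ish column it
    belongs to; groups share a letter iff their pair is in
    ``not_different``.
    """
    columns: list[set[str]] = []
    for g in groups:
        placed = False
        for col in columns:
            if all(frozenset((g, other)) in not_different for other in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    # ensure every non-significant pair shares some column
    for a_i, a in enumerate(groups):
        for b in groups[a_i + 1 :]:
            if frozenset((a, b)) in not_different and not any(
                a in col and b in col for col in columns
            ):
                columns.append({a, b})
    # absorb columns contained in others
    columns = [
        col
        for i, col in enumerate(columns)
        if not any(i != j and col < other for j, other in enumerate(columns))
    ]
    # deduplicate
    uniq: list[set[str]] = []
    for col in columns:
        if col not in uniq:
            uniq.append(col)
    uniq.sort(key=lambda col: min(groups.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(uniq):
        for g in groups:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> HSDResult:
    """One-way ANOVA F test plus Tukey(-Kramer) HSD letters.

    ``groups`` maps label -> vector of values (e.g., per-chain
    alphaE/alphaD estimates per era); unequal sizes are allowed.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(groups[g], float) for g in labels]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs >= 2 values")
    f_stat, p_val = stats.f_oneway(*arrs)
    values = np.concatenate(arrs)
    codes = np.concatenate([[g] * len(a) for g, a in zip(labels, arrs)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    not_different: set[frozenset] = set()
    pairwise = []
    res = tk.summary().data[1:]
    for row in res:
        g1, g2, _, p_adj, _, _, reject = row
        pairwise.append((str(g1), str(g2), float(p_adj), bool(reject)))
        if not reject:
            not_different.add(frozenset((str(g1), str(g2))))
    letters = _compact_letters(labels, not_different)
    return HSDResult(
        group_means={g: float(a.mean()) for g, a in zip(labels, arrs)},
        letters=letters,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        alpha=alpha,
        pairwise=pairwise,
    )


def diversity_regression(
    pi: np.ndarray, potato_prop: np.ndarray, era_label: str | int | None = None
) -> RegressionResult:
    """OLS of per-site nucleotide diversity on crop-cover proportion."""
    result = _ols(np.asarray(pi, float), np.asarray(potato_prop, float))
    if era_label is not None:
        logger.info(
            "diversity ~ cover (%s): slope=%.4g p=%.3g R2=%.3f",
            era_label, result.slope, result.p_value, result.r_squared,
        )
    return result


def fst_vs_diversity(fst: PairwiseMatrix, pi: np.ndarray) -> RegressionResult:
    """OLS of pairwise FST on the mean nucleotide diversity of each pair.

    The predictor for pair (i, j) is (pi_i + pi_j)/2 — "average
    nucleotide diversity between sites" read as the mean of the two site
    values.
    """
    pi = np.asarray(pi, float)
    if len(pi) != fst.n:
        raise ValueError(f"{len(pi)} diversity values for {fst.n} sites")
    iu = np.triu_indices(fst.n, k=1)
    pred = (pi[iu[0]] + pi[iu[1]]) / 2.0
    return _ols(fst.upper_triangle(), pred)


def plot_regression(x, y, result: RegressionResult, path, xlabel="", ylabel="") -> None:
    """Scatter + fitted line; optional figure output (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="C1")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"slope={result.slope:.3g}, p={result.p_value:.3g}, R$^2$={result.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
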