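"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the implementation: rasterized areas instead of polygon clipping,
Monte-Carlo point classification instead of line-polygon intersection,
allele-pair enumeration instead of closed forms, ANOVA sums of squares
on allele indicators instead of the moment formulas, adaptive
quadrature instead of fixed-order Gauss-Legendre, and a hand-coded
Tukey-Kramer test built directly on the studentized-range distribution.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, stats
from shapely import contains_xy

from landgen.popgen import MISSING


# ---------------------------------------------------------------------------
# geometry

def rasterized_intersection_area(geom_a, geom_b, cell: float = 1.0) -> float:
    """Area of a ∩ b by counting cell centers inside both polygons."""
    minx = min(geom_a.bounds[0], geom_b.bounds[0])
    miny = min(geom_a.bounds[1], geom_b.bounds[1])
    maxx = max(geom_a.bounds[2], geom_b.bounds[2])
    maxy = max(geom_a.bounds[3], geom_b.bounds[3])
    xs = np.arange(minx + cell / 2, maxx, cell)
    ys = np.arange(miny + cell / 2, maxy, cell)
    gx, gy = np.meshgrid(xs, ys)
    inside = contains_xy(geom_a, gx.ravel(), gy.ravel()) & contains_xy(
        geom_b, gx.ravel(), gy.ravel()
    )
    return float(inside.sum()) * cell * cell


def mc_lrt(a, b, county_map, era: int, n_points: int = 100_000) -> float:
    """LRT by classifying points along the transect (midpoint sampling)."""
    ts = (np.arange(n_points) + 0.5) / n_points
    xs = a.x + ts * (b.x - a.x)
    ys = a.y + ts * (b.y - a.y)
    z = np.zeros(n_points)
    claimed = np.zeros(n_points, dtype=bool)
    for cid in sorted(county_map.counties):
        inside = contains_xy(county_map.counties[cid], xs, ys) & ~claimed
        z[inside] = county_map.proportion(era, cid)
        claimed |= inside
    denom = z.mean()
    return np.inf if denom == 0 else 1.0 / denom


# ---------------------------------------------------------------------------
# population genetics

def fst_anova_oracle(calls: np.ndarray, pop_labels: list[str], pop_a: str, pop_b: str) -> float:
    """Weir-Cockerham two-deme FST via literal ANOVA on allele indicators.

    Decomposes allele-indicator variation into population / individual /
    within-individual sums of squares per locus, converts mean squares to
    variance components, and combines across loci as ratio of averages.
    """
    labels = np.asarray(pop_labels)
    num = den = 0.0
    for l in range(calls.shape[1]):
        groups = []
        for pop in (pop_a, pop_b):
            col = calls[labels == pop, l]
            col = col[col != MISSING]
            if len(col) < 2:
                groups = []
                break
            groups.append(col)
        if not groups:
            continue
        r = 2
        n = np.array([len(g) for g in groups], float)
        N = n.sum()
        # allele indicators: genotype g -> alleles contributing g/2 mean
        ybar_ij = [g / 2.0 for g in groups]
        ybar_i = np.array([yb.mean() for yb in ybar_ij])
        ybar = sum(yb.sum() for yb in ybar_ij) / N
        ssp = sum(2 * n_i * (yi - ybar) ** 2 for n_i, yi in zip(n, ybar_i))
        ssi = sum(2 * ((yb - yi) ** 2).sum() for yb, yi in zip(ybar_ij, ybar_i))
        ssg = 0.0
        for g in groups:
            # within-individual SS: het individual has alleles {0,1}, mean 1/2
            ssg += 0.25 * 2 * (g == 1).sum()
        msp = ssp / (r - 1)
        msi = ssi / (N - r)
        msg = ssg / N
        nc = (N - (n**2).sum() / N) / (r - 1)
        sa = (msp - msi) / (2 * nc)
        sb = (msi - msg) / 2.0
        sc = msg
        num += sa
        den += sa + sb + sc
    return num / den


def pi_pairwise_oracle(calls: np.ndarray, pop_labels: list[str], pop: str, total_sites: int) -> float:
    """Nucleotide diversity by enumerating all allele pairs per locus."""
    labels = np.asarray(pop_labels)
    total = 0.0
    for l in range(calls.shape[1]):
        col = calls[labels == pop, l]
        col = col[col != MISSING]
        alleles = []
        for g in col:
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
        if len(alleles) < 2:
            continue
        pairs = list(itertools.combinations(alleles, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / total_sites


# ---------------------------------------------------------------------------
# model layer

def quad_marginal_oracle(alt: int, m: int, mu: float, sigma2: float, phi: float) -> float:
    """Marginal log likelihood of one count by adaptive quadrature."""
    sd = np.sqrt(sigma2)

    def integrand(th):
        dens = stats.truncnorm.pdf(th, (0 - mu) / sd, (1 - mu) / sd, loc=mu, scale=sd)
        return stats.betabinom.pmf(alt, m, th * phi, (1 - th) * phi) * dens

    val, _ = integrate.quad(integrand, 1e-12, 1 - 1e-12, limit=200)
    return float(np.log(val))


def tukey_kramer_oracle(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """Pairwise Tukey-Kramer rejections from the studentized range."""
    labels = list(groups)
    arrs = [np.asarray(groups[g], float) for g in labels]
    k = len(arrs)
    n = np.array([len(a) for a in arrs])
    means = np.array([a.mean() for a in arrs])
    dfw = int(n.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / dfw
    qcrit = stats.studentized_range.ppf(1 - alpha, k, dfw)
    rejects = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / n[i] + 1 / n[j]))
            q = abs(means[i] - means[j]) / se
            rejects[frozenset((labels[i], labels[j]))] = q > qcrit
    return rejects
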