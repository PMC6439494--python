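"""Genotype matrices, SNP filters, and population-genetic statistics.

Diploid genotypes are stored as counts of the designated alternate allele
(0/1/2, with -1 for missing).  The statistics implemented here are the
standard moment estimators used in reduced-representation SNP studies:

* pairwise FST between two populations via the Weir & Cockerham (1984)
  two-deme variance-component estimator, combined across loci as a ratio
  of averages (sum of a-components over sum of a+b+c) — the estimator
  behind the usual "Weir and Hill" pairwise FST of landscape-genetic
  software;
* nucleotide diversity (pi) as the expected per-site mismatch between two
  alleles sampled without replacement, averaged over all genotyped sites
  (monomorphic sites enter the denominator via ``total_sites``);
* observed heterozygosity as the fraction of heterozygous calls per site,
  averaged over ``total_sites``;
* the folded site frequency spectrum of minor-allele counts, the input
  of stairway-type demographic inference.

Filters mirror a typical GBS curation: minor-allele-frequency and
per-locus missingness thresholds, then deterministic modal imputation
(each missing call replaced by the most frequent genotype at that locus
within its population).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype code for a missing call
MISSING = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeFormatError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype codes with population labels.

    ``calls[i, l]`` counts copies of the alternate allele for individual
    ``i`` at locus ``l`` (0, 1, 2) or is -1 when missing.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = len(self.individual_ids), len(self.locus_ids)
        if self.calls.shape != (n, L):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} != ({n}, {L})"
            )
        if len(self.population_labels) != n:
            raise GenotypeFormatError("one population label per individual required")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise GenotypeFormatError(f"invalid genotype codes {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def population_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.population_labels])
        if not mask.any():
            raise KeyError(f"unknown population label {pop!r}")
        return mask

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            population_labels=self.population_labels,
            locus_ids=[l for l, k in zip(self.locus_ids, keep) if k],
            calls=self.calls[:, keep],
        )


@dataclass
class AlleleCountTable:
    """Per population x locus alternate-allele counts and allele numbers."""

    populations: list[str]
    locus_ids: list[str]
    alt_count: np.ndarray   # (P, L) ints
    allele_number: np.ndarray  # (P, L) ints, 2 * genotyped individuals

    def __post_init__(self) -> None:
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.allele_number = np.asarray(self.allele_number, dtype=np.int64)
        if (self.alt_count > self.allele_number).any():
            raise ValueError("alt_count exceeds allele_number")
        if (self.allele_number % 2 != 0).any():
            raise ValueError("allele_number must be even (diploid calls)")


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum: counts of loci per minor-allele count."""

    population_label: str
    bins: np.ndarray  # length 2n+1; entries beyond n are zero
    allele_number: int

    @property
    def n_loci(self) -> int:
        return int(self.bins.sum())


# ---------------------------------------------------------------------------
# loading

def _genotypes_from_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        loci.append(f"{var.CHROM}:{var.POS}")
        rows.append(remap[np.asarray(var.gt_types)])
    if n_multi:
        logger.info("%s: skipped %d multiallelic record(s)", path, n_multi)
    if not rows:
        raise GenotypeFormatError(f"{path}: no parsable biallelic SNP records")
    calls = np.column_stack(rows) if rows else np.empty((len(ids), 0), dtype=np.int8)
    return GenotypeMatrix(
        individual_ids=ids,
        population_labels=[""] * len(ids),
        locus_ids=loci,
        calls=calls,
    )


def _genotypes_from_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise GenotypeFormatError(
            f"{path}: need individual_id, population_label plus >=1 locus column"
        )
    first_two = list(df.columns[:2])
    if first_two != ["individual_id", "population_label"]:
        raise GenotypeFormatError(
            f"{path}: first two columns must be individual_id, population_label "
            f"(got {first_two})"
        )
    loci = list(df.columns[2:])
    raw = df[loci].to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for code in (0, 1, 2):
        calls[(raw == code) | (raw == str(code)) | (raw == float(code))] = code
    # anything not 0/1/2/NA-like is an error
    recognized = (calls != MISSING)
    na_like = pd.isna(raw) | np.isin(raw, ["NA", "na", ".", ""])
    bad = ~(recognized | na_like)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeFormatError(
            f"{path}: unrecognized genotype {raw[i, j]!r} "
            f"(individual {df.iloc[i, 0]!r}, locus {loci[j]!r})"
        )
    return GenotypeMatrix(
        individual_ids=[str(v) for v in df.iloc[:, 0]],
        population_labels=[str(v) for v in df.iloc[:, 1]],
        locus_ids=loci,
        calls=calls,
    )


def load_genotypes(path, format: str = "vcf", populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load diploid genotypes from a VCF (GT field) or a genotype CSV.

    ``populations`` optionally maps individual_id -> population_label
    (required for VCF input if labels matter; the CSV format carries its
    own labels in the second column).
    """
    if format == "vcf":
        g = _genotypes_from_vcf(path)
    elif format == "csv":
        g = _genotypes_from_csv(path)
    else:
        raise ValueError(f"format must be 'vcf' or 'csv', got {format!r}")
    if populations is not None:
        missing = [i for i in g.individual_ids if i not in populations]
        if missing:
            raise GenotypeFormatError(f"no population label for individuals {missing[:5]}")
        g = GenotypeMatrix(
            individual_ids=g.individual_ids,
            population_labels=[populations[i] for i in g.individual_ids],
            locus_ids=g.locus_ids,
            calls=g.calls,
        )
    return g


# ---------------------------------------------------------------------------
# filters and imputation

def _pooled_alt_freq(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency over all non-missing calls, pooled across pops."""
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
    an = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(an > 0, alt / an, np.nan)
    return freq, an


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep loci with pooled minor-allele frequency >= threshold."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    freq, _ = _pooled_alt_freq(g.calls)
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        keep = maf >= threshold
    keep = np.where(np.isnan(maf), threshold == 0.0, keep).astype(bool)
    removed = g.n_loci - int(keep.sum())
    if removed:
        logger.info("filter_maf(%.3g): removed %d of %d loci", threshold, removed, g.n_loci)
    if keep.sum() == 0:
        logger.warning("filter_maf removed every locus")
    return g.subset_loci(keep)


def filter_missing(g: GenotypeMatrix, threshold: float = 0.30) -> GenotypeMatrix:
    """Keep loci whose missing-call fraction is <= threshold (boundary kept)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"missingness threshold must be in (0, 1], got {threshold}")
    frac = (g.calls == MISSING).mean(axis=0)
    keep = frac <= threshold + 1e-12
    removed = g.n_loci - int(keep.sum())
    if removed:
        logger.info("filter_missing(%.3g): removed %d of %d loci", threshold, removed, g.n_loci)
    return g.subset_loci(keep)


def _modal_code(values: np.ndarray) -> int:
    """Most frequent genotype code; ties broken toward the smaller code."""
    counts = Counter(int(v) for v in values if v != MISSING)
    if not counts:
        return MISSING
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def impute_mode(g: GenotypeMatrix, scope: str = "population") -> GenotypeMatrix:
    """Replace missing calls by the modal genotype within scope.

    A stand-in for haplotype-based imputation: each missing call becomes
    the most frequently observed genotype at that locus, computed within
    the individual's population (scope="population") or over everyone
    (scope="global").  An all-missing locus within a population falls
    back to the global mode; a locus missing in every individual is an
    error.
    """
    if scope not in ("population", "global"):
        raise ValueError(f"scope must be 'population' or 'global', got {scope!r}")
    calls = g.calls.copy()
    for l in range(g.n_loci):
        col = calls[:, l]
        if not (col == MISSING).any():
            continue
        gmode = _modal_code(col)
        if gmode == MISSING:
            raise ValueError(f"locus {g.locus_ids[l]!r} is missing in every individual")
        if scope == "global":
            col[col == MISSING] = gmode
            continue
        for pop in g.populations:
            mask = g.population_mask(pop)
            sub = col[mask]
            if not (sub == MISSING).any():
                continue
            pmode = _modal_code(sub)
            if pmode == MISSING:
                logger.warning(
                    "locus %r all-missing in population %r; global mode used",
                    g.locus_ids[l], pop,
                )
                pmode = gmode
            sub[sub == MISSING] = pmode
            col[mask] = sub
    return GenotypeMatrix(
        individual_ids=g.individual_ids,
        population_labels=g.population_labels,
        locus_ids=g.locus_ids,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# allele counts

def allele_counts(g: GenotypeMatrix) -> AlleleCountTable:
    """Tally per-population alternate-allele counts from non-missing calls."""
    pops = g.populations
    P, L = len(pops), g.n_loci
    alt = np.zeros((P, L), dtype=np.int64)
    an = np.zeros((P, L), dtype=np.int64)
    for k, pop in enumerate(pops):
        sub = g.calls[g.population_mask(pop)]
        obs = sub != MISSING
        alt[k] = np.where(obs, sub, 0).sum(axis=0)
        an[k] = 2 * obs.sum(axis=0)
    return AlleleCountTable(
        populations=pops, locus_ids=list(g.locus_ids), alt_count=alt, allele_number=an
    )


# ---------------------------------------------------------------------------
# statistics

def _pop_locus_summaries(g: GenotypeMatrix, pop: str):
    """Per-locus (n genotyped individuals, alt frequency, het proportion)."""
    sub = g.calls[g.population_mask(pop)]
    obs = sub != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, sub, 0).sum(axis=0).astype(float)
    het = ((sub == 1) & obs).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def weir_cockerham_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) a, b, c components for two demes.

    Inputs are per-locus sample sizes (genotyped diploid individuals),
    alternate-allele frequencies and observed-heterozygote proportions
    for each deme.  Returns arrays (a, b, c); FST is sum(a)/sum(a+b+c).
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nsum = n1 + n2
    nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / nsum
    inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir & Cockerham two-deme FST, ratio of averages.

    Loci where either population has fewer than 2 genotyped individuals
    are skipped.  The estimator can be slightly negative under no
    differentiation.
    """
    na, pa, ha = _pop_locus_summaries(g, pop_a)
    nb, pb, hb = _pop_locus_summaries(g, pop_b)
    if (na >= 2).sum() == 0 or (nb >= 2).sum() == 0:
        raise ValueError("both populations need >= 2 genotyped individuals")
    usable = (na >= 2) & (nb >= 2)
    a, b, c = weir_cockerham_components(
        na[usable], pa[usable], ha[usable], nb[usable], pb[usable], hb[usable]
    )
    denom = float(np.sum(a + b + c))
    if denom == 0.0:
        raise ValueError(
            f"no usable polymorphic loci between {pop_a!r} and {pop_b!r}"
        )
    return float(np.sum(a)) / denom


def fst_matrix(g: GenotypeMatrix, sites_order: list[str] | None = None):
    """All pairwise FST values as a PairwiseMatrix (zero diagonal)."""
    from .resistance import PairwiseMatrix

    pops = sites_order if sites_order is not None else g.populations
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_fst(g, pops[i], pops[j])
    return PairwiseMatrix(site_ids=list(pops), values=vals, label="fst")


def nucleotide_diversity(g: GenotypeMatrix, pop: str, total_sites: int) -> float:
    """Nei & Li per-site nucleotide diversity within one population.

    pi = (1/total_sites) * sum_l 2 p (1-p) m/(m-1) with m the number of
    genotyped alleles at locus l — the probability that two alleles drawn
    without replacement differ, summed over variant loci and averaged
    over all ``total_sites`` genotyped sites (monomorphic ones included
    in the denominator).  Loci with fewer than 2 genotyped alleles are
    skipped with a warning.
    """
    if total_sites < g.n_loci:
        raise ValueError(
            f"total_sites ({total_sites}) must be >= number of loci ({g.n_loci})"
        )
    n, p, _ = _pop_locus_summaries(g, pop)
    m = 2.0 * n
    usable = m >= 2
    if (~usable).any():
        logger.warning(
            "nucleotide_diversity %r: skipped %d locus/loci with < 2 genotyped alleles",
            pop, int((~usable).sum()),
        )
    pu, mu = p[usable], m[usable]
    per_locus = 2.0 * pu * (1.0 - pu) * mu / (mu - 1.0)
    return float(per_locus.sum()) / float(total_sites)


def observed_heterozygosity(g: GenotypeMatrix, pop: str, total_sites: int) -> float:
    """Mean per-site fraction of heterozygous calls, over total_sites."""
    if total_sites < g.n_loci:
        raise ValueError(
            f"total_sites ({total_sites}) must be >= number of loci ({g.n_loci})"
        )
    n, _, h = _pop_locus_summaries(g, pop)
    usable = n > 0
    return float(h[usable].sum()) / float(total_sites)


def folded_sfs(g: GenotypeMatrix, pop: str) -> FoldedSFS:
    """Folded SFS of minor-allele counts for one population.

    Requires an equal allele number at every locus (impute first); the
    spectrum is the histogram of min(alt_count, 2n - alt_count).
    """
    sub = g.calls[g.population_mask(pop)]
    if (sub == MISSING).any():
        raise ValueError(
            "missing calls give unequal allele numbers across loci; "
            "run impute_mode first"
        )
    m = 2 * sub.shape[0]
    alt = sub.sum(axis=0, dtype=np.int64)
    minor = np.minimum(alt, m - alt)
    bins = np.bincount(minor, minlength=m + 1)
    return FoldedSFS(population_label=pop, bins=bins, allele_number=m)


def diversity_table(g: GenotypeMatrix, total_sites: int) -> pd.DataFrame:
    """Tidy per-population pi and observed heterozygosity."""
    rows = [
        {
            "population": pop,
            "pi": nucleotide_diversity(g, pop, total_sites),
            "observed_heterozygosity": observed_heterozygosity(g, pop, total_sites),
        }
        for pop in g.populations
    ]
    return pd.DataFrame(rows)
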