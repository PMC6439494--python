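# Methods

`landgen` reconstructs, as a tested pipeline, a historical landscape
genetics analysis: how much of the allele-frequency differentiation among
populations of a crop pest is explained by the historical distribution of
its host crop, relative to plain geographic distance. This note records
the models, the numerical choices, and the limits of what the synthetic
experiments show.

## Census harmonization

County censuses report crop area per county, but county boundaries change
between eras. Historic values are re-expressed on a reference (modern)
county map by polygon overlap:

    value(R) = Σ_i a_i · p_i,   a_i = area(i ∩ R) / area(i),

where `p_i` is the proportion of historic county `i` in the crop. This
overlap sum is the default ("printed") mode. It is not a proper
area-weighted mean: merging two fully-covered historic counties into one
reference county yields `p_1 + p_2`, which can exceed 1. The pipeline
reports such values verbatim and logs them; a "weighted" mode computing
`Σ_i area(i ∩ R)·p_i / area(R)` (a true areal interpolation bounded in
[0, 1]) is selectable in config, and the mode is recorded in every output
row. All geometry must arrive in one planar projection in meters; inputs
whose coordinates all fall inside |x| ≤ 360, |y| ≤ 90 are rejected as
probable lon/lat, and self-intersecting polygons are repaired by
zero-width buffering (logged). The pipeline never reprojects.

## Landscape resistance to transmission (LRT)

For two sites the transect is the straight line between them, cut into
segments by the county polygons it crosses:

    LRT = 1 / Σ_i (Z_i · L_i / L_T),

with `Z_i` the crop proportion of county `i` for the chosen era, `L_i`
the segment length inside county `i`, and `L_T` the total length. LRT is
1 when the path crosses saturated cover, ≥ 1 whenever all `Z_i` ≤ 1, and
+∞ when no crop lies anywhere along the path (logged; the model layer
replaces infinities by 10× the largest finite entry before
standardization, configurable). Transect portions covered by no county
contribute Z = 0 — the resistance of crop absence. A transect lying
exactly on a shared county boundary is assigned to the lexicographically
smaller county id (deterministic, logged). "Shortest path" is the
straight line; least-cost or circuit-theory resistance is out of scope.
Resistance and distance matrices are standardized by dividing
off-diagonal entries by the sample SD of the upper triangle, each matrix
(era) separately.

## Population-genetic statistics

Genotypes are diploid alternate-allele counts (0/1/2, missing allowed).
Curation mirrors a typical GBS workflow: drop loci with pooled minor
allele frequency < 5% (pooled over all populations of a region), drop
loci with > 30% missing calls (the exactly-30% locus is retained), then
impute each remaining missing call with the most frequent genotype at
that locus within the individual's population (global scope available;
ties go to the smaller code; an all-missing population falls back to the
global mode). This deterministic modal imputation stands in for
haplotype-clustering imputation, for which no linkage model is available
here; it ignores linkage entirely, and that is a real limitation for
rare-variant-sensitive downstream uses.

* **Pairwise FST** is the Weir & Cockerham (1984) two-deme
  variance-component estimator, combined across loci as a ratio of
  averages (Σ a / Σ (a+b+c)) — the standard implementation behind the
  "Weir and Hill" pairwise FST reported by landscape-genetic software.
  Loci where either deme has fewer than two genotyped individuals are
  skipped. The estimator may be slightly negative under no
  differentiation.
* **Nucleotide diversity** per population is
  π = (1/total_sites) Σ_l 2p̂(1−p̂)·m/(m−1) with `m` the number of
  genotyped alleles at the locus — the exact mean mismatch over allele
  pairs sampled without replacement. `total_sites` (all genotyped sites,
  monomorphic included) is a config input, since it depends on the
  upstream assembly; loci with fewer than two genotyped alleles are
  skipped with a warning. A single heterozygous diploid therefore has
  π = 1 at that site, matching pair enumeration.
* **Observed heterozygosity** is the per-locus fraction of heterozygous
  calls summed over loci and divided by `total_sites`.
* **Folded SFS** per population is the histogram of per-locus minor
  allele counts min(alt, 2n − alt), requiring equal allele numbers
  (i.e., run after imputation).

## The allele-frequency covariance model

Differentiation is modeled through a parametric covariance of latent
per-locus population frequencies:

    Ω[i,j] = (1/α0) · exp(−(αD·D[i,j] + Σ_k αE_k·E_k[i,j])^α2),  Ω[i,i] = 1/α0,

with D standardized geographic distance and E_k standardized resistance
for era k. Per locus, latent frequencies are multivariate normal with
mean μ_l and covariance μ_l(1−μ_l)·Ω, truncated to [0, 1]; observed
alternate-allele counts per population are beta-binomial around the
latent frequency with per-population dispersion φ_p. The headline
statistic is αE/αD, the effect of landscape resistance relative to
geographic distance. The per-era model uses one E; the all-era model
puts one αE_k per era in a single Ω.

Choices the framework leaves open, fixed here:

* **Priors.** Exponential(1) on αD and each αE — the covariates are
  SD-standardized, so rate 1 is weakly informative on the scale of the
  data. This is load-bearing: with a flat prior on log effect sizes
  there is an enormous equal-likelihood plateau (once the exponent
  saturates, Ω is numerically diagonal and the likelihood no longer
  changes), and the ratio simply diffuses over prior volume.
  Exponential(0.01) on α0; log-flat on φ_p; everything restricted to
  [1e-8, 1e8]. μ_l is uniform on (0, 1). α2 is fixed at 1 (estimable by
  config, held fixed in all analyses here).
* **Parameterization.** The sampler works in the scale-non-centered form
  θ[p,l] = μ_l + α0^(−1/2)·ε[p,l] with ε ~ MVN(0, μ(1−μ)R), an exact
  reparameterization. In the centered form the joint density grows
  without bound as α0 rises and the latent field shrinks toward μ (a
  funnel), which traps random-walk samplers in a regime where all count
  variation is mis-attributed to the beta-binomial layer.
* **Truncation.** Proposals are clipped into [1e-6, 1 − 1e-6] before the
  likelihood; the box-normalization constant of the truncated MVN (which
  depends on Ω) is omitted. At the α0 values relevant here the truncated
  mass is tiny, but this is an approximation.
* **Updates.** Metropolis-within-Gibbs: random walks on the logs of α0,
  αD, αE_k, φ_p; single-site walks on ε over a rotating block of loci
  per step; independence proposals for μ_l from a Beta centred on the
  pooled empirical frequency (concentration 20). One extra "exchange"
  move per covariate proposes (log αD − δ, log αE_k + δ) jointly: αD and
  αE are strongly anti-correlated when D and E correlate, and
  single-parameter walks cross between their trade-off modes very
  slowly without it. A second interweaving move shifts μ_l with a
  compensating common shift of the locus's ε column so that θ — and
  hence the likelihood — is unchanged, at O(P) cost. This move is
  load-bearing: the pooled empirical mean absorbs the shared component
  of the frequency field, leaving residual correlations that are
  slightly negative (which the covariance model cannot produce); the
  landscape-effect mode requires μ to drift off that anchor, and
  without the interweave chains sit in a metastable no-effect mode for
  50k–200k steps before the locus-by-locus reorganization completes.
  α0 is the expensive update (it touches the whole likelihood) and
  takes its rotation slot every third cycle.
* **Initialization.** ε starts at the standardized empirical deviations;
  μ at the pooled empirical frequency; φ at 50; α0 at 10. αD and αE
  start from a method-of-moments fit: pairwise correlations of
  empirical deviations fall, to first order, linearly in
  αD·D + Σ αE·E, so OLS of the correlation on [1, D, E_k] gives
  (sign-flipped, clipped) slopes that are rescaled to a moderate mean
  exponent of 0.5. The starting R is then checked for conditioning —
  a nearly flat exponent makes R a near-ones matrix — and the starting
  effect sizes are scaled up until it factorizes sanely; the same
  conditioning guard inside the sampler rejects proposals whose R is
  numerically singular rather than let an ill-conditioned inverse
  poison the cached quadratic forms.
* **Tuning.** Proposal scales adapt every 500 steps during the first 20%
  of the chain (discarded window) toward an acceptance rate in the
  middle of the 20–70% band, then freeze; post-tuning rates are reported
  per block and a warning is recorded when a block lands outside the
  band.
* **Estimates.** The "final estimate" of a chain is the posterior
  median of αE/αD over the retained window (second half of the chain,
  after thinning). The ratio of two log-scale parameters is heavy-
  tailed — a few retained samples with αD near its prior floor inflate
  a posterior mean by orders of magnitude, while medians are stable —
  so the median is used wherever a chain is reduced to one number.
  Per-era summaries report mean and SE of these per-chain estimates
  across chains and attach compact Tukey-HSD letters.
  Convergence is assessed with the potential scale reduction factor
  (between- vs within-chain variance, with a Brooks–Gelman-style upper
  confidence bound).

Desk-scale run configuration: 4 chains × 50,000 steps, thinning 10,
latent block 1/32 of loci per step. A survey-scale configuration
(30 chains × 4,000,000 steps) is available through the same config but
is not exercised by the tests. The ratio posterior is heavy-tailed —
pooled posterior medians are far more stable than means across chains,
and per-chain means can differ by an order of magnitude even when
medians agree; the regression and HSD layers therefore see per-chain
estimates whose spread is itself informative about identifiability.

## Downstream statistics

Stage 1 regresses vectorized upper-triangle FST on standardized distance;
stage 2 regresses the stage-1 residuals on standardized resistance. Both
are plain OLS, reproducing the analysis convention; matrix pairs are not
independent, so these p-values are anti-conservative, and a Mantel-style
permutation p-value is available behind a flag (off by default).
Effect-ratio differences among eras use one-way ANOVA plus Tukey HSD at
α = 0.05 (Tukey–Kramer for unequal chain counts) with an
insert-and-absorb compact letter display. "Average nucleotide diversity
between sites" is read as the mean of the two site values. Predictors
are standardized before vectorizing triangles.

## Synthetic data

The generator produces exactly the structure the model assumes:
axis-aligned rectangular county grids (closed-form segment lengths make
exact LRT oracles possible), per-era cover patterns (uniform, linear
gradient, or concentrated patch), sites at the centers of distinct
seeded-randomly chosen counties (one population per site), latent
frequencies drawn from the truncated-MVN covariance model (rejection
sampling, 100 tries then clipping, logged), and genotypes drawn
binomial(2, q) around one Beta(θφ, (1−θ)φ) draw per population × locus —
so population allele totals are marginally beta-binomial, matching the
observation layer. Missing calls are injected independently.

Default study conditions mirror a regional GBS survey of an insect pest:
8 populations × 12 diploids, 500–1,000 biallelic SNPs, three census eras,
α0 = 20 (pairwise differentiation on the order of a few percent),
dispersion φ = 100, 2% missing calls, and a true αE/αD of 10 in the
"strong" scenario (αD = 0.05, αE = 0.5 against SD-standardized
covariates). The `era_contrast` scenario drives genotypes with the
contemporary era's resistance only, over three deliberately distinct
cover patterns (x-gradient, y-gradient, concentrated patch), mimicking a
contemporary-over-historic contrast. Cover floors of 0.02 keep LRT
finite.

What passing tests do and do not show: the generator draws from the
inference model itself (plus its own landscape geometry), so parameter
recovery demonstrates the estimator and sampler are correct and
identifiable under the model's assumptions at desk scale. It does not
validate the model against real GBS data — no linkage, no selection, no
coalescent noise, no shared demographic history beyond the covariance,
and no genotyping-error structure beyond beta-binomial dispersion.

## Problem sizes

Test and acceptance runs use 8 populations, 500 loci, 4 chains × 50,000
steps per model; the parameter-recovery experiment repeats the
strong-vs-null comparison over 20 generator seeds, and the acceptance
script runs one strong/null pair plus the three-era contrast at the same
size. Geometric oracles run on toy maps ≤ 1 km² at 1 m rasterization and
10⁵-point transect classification.

## Known limitations

* The printed harmonization formula can exceed 1 by construction; the
  package surfaces rather than hides this.
* Modal imputation ignores linkage; folded SFS from imputed data will
  understate rare variation relative to haplotype-aware imputation.
* OLS on pairwise matrices ignores non-independence (by design, for
  fidelity to the analysis convention).
* The αE/αD posterior is heavy-tailed and its absolute scale depends on
  the covariate standardization and the effect-size prior; comparisons
  across eras (same standardization, same prior) are the robust output,
  absolute ratios less so.
* With |corr(D, E)| > 0.99 the ratio is unidentified; the model layer
  warns and results should be read as such.
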