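# landgen

Historical landscape genetics for crop-pest populations: does the
*historical* distribution of a host crop explain today's genetic
differentiation better than plain geographic distance?

`landgen` is aimed at landscape geneticists working with county-level
agricultural census records and reduced-representation SNP data. It
provides, as one configuration-driven pipeline:

* **Census harmonization** — crop-cover proportions reported on historic
  county boundaries re-expressed on a modern reference map via the
  polygon-overlap sum Σᵢ aᵢ·pᵢ (with a bounded area-weighted variant).
* **Landscape resistance to transmission (LRT)** — for each pair of
  sampling sites, `LRT = 1 / Σᵢ (Zᵢ·Lᵢ/L_T)`: the inverse of the
  path-length-weighted mean crop proportion along the straight line
  between the sites, computed per census era.
* **Population-genetic statistics** — Weir–Cockerham two-deme pairwise
  F_ST (ratio of averages across loci), nucleotide diversity π, observed
  heterozygosity, folded site frequency spectra, and the standard GBS
  curation (MAF ≥ 5%, ≤ 30% missingness, modal imputation).
* **A Bayesian allele-frequency covariance model** — latent per-locus
  population frequencies with covariance

      Ω[i,j] = (1/α0)·exp(−(αD·D[i,j] + Σₖ αEₖ·Eₖ[i,j])^α2)

  observed through beta-binomial allele counts with per-population
  dispersion; fitted by a numba-accelerated Metropolis-within-Gibbs
  sampler with auto-tuned proposals, Gelman–Rubin diagnostics, and
  per-era / all-era variants. The headline statistic is **αE/αD**, the
  effect of landscape resistance relative to geographic distance.
* **The downstream battery** — residual regression of F_ST on resistance
  after distance, ANOVA + Tukey HSD letters for αE/αD across census
  eras, and diversity regressions.
* **A synthetic-data generator** — rectangular county landscapes, census
  histories, and genotypes drawn from the covariance model itself, so
  the entire pipeline is exercisable and testable with no downloads.

## Worked example

Generate a three-era synthetic study in which genotypes are driven by
the contemporary era's resistance only, run the full pipeline, and read
the effect summary:

```python
import dataclasses, pandas as pd
from landgen.ibr_model import IBRConfig
from landgen.pipeline import PipelineConfig, run
from landgen.synthetic_data import make_fixture

bundle = make_fixture("era_contrast", "scratch/fixture", seed=0)
config = PipelineConfig(
    polygons={era: str(bundle / "counties.geojson") for era in (1860, 1910, 2012)},
    census=str(bundle / "census.csv"),
    sites=str(bundle / "sites.csv"),
    genotypes=str(bundle / "genotypes.vcf"),
    populations=str(bundle / "populations.csv"),
    eras=[1860, 1910, 2012],
    outdir="scratch/run",
    ibr=IBRConfig(n_steps=50_000, n_chains=4, thin=10, seed=100),
)
outdir = run(config)
print(pd.read_csv(outdir / "effect_summary.csv"))          # per-era models
print(pd.read_csv(outdir / "effect_summary_all_eras.csv"))  # one joint model
```

This run prints:

```
  covariate  mean_ratio  standard_error hsd_group
0      1860    0.354720        0.018480         a
1      1910   82.148099       50.892769         a
2      2012   10.826899        0.346506         a
  covariate  mean_ratio  standard_error hsd_group
0      1860    0.233256        0.033934         a
1      1910    0.587001        0.061542         a
2      2012    6.254950        0.265767         b
```

Read: in the per-era models, all four chains agree that 2012 — the era
whose resistance actually generated the genotypes (true αE/αD = 10) —
has a ratio near 11 with a small standard error, and that 1860 has
essentially none. The 1910-only model is the cautionary tale: its
resistance surface is only partially correlated with the true one, two
of four chains collapse αD toward zero, and the ratio (a quotient of
two effect sizes) explodes to a mean of 82 with an SE almost as large —
exactly the huge-mean/huge-SE signature such ratio statistics show in
real analyses when distance contributes nothing. The all-eras model,
which fits one covariance with all three resistance surfaces at once,
resolves the ambiguity: 2012 keeps a large, tight ratio and alone earns
HSD letter "b". The run directory also contains the harmonized census
tables, distance and per-era resistance matrices, F_ST / diversity /
folded-SFS tables, per-chain ratio estimates, the residual-regression
battery, and a manifest with input hashes and the seed.

The same thing from the shell:

```bash
landgen simulate era_contrast --outdir scratch/fixture --seed 0
landgen run-all --config config.yaml --seed 100
```

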