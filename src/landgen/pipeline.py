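"""Configuration-driven orchestration of the full analysis, plus the CLI.

Stages: census load -> boundary harmonization -> per-era resistance and
distance matrices -> SNP filters and imputation -> FST / diversity /
folded SFS -> per-era and all-era covariance models -> effect summary
with Tukey HSD -> residual and diversity regressions.  Every run writes
its artifacts plus a manifest (input hashes, seed, package version) into
the output directory; a failure aborts with the stage name and leaves a
partial manifest behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from .association import diversity_regression, fst_vs_diversity, residual_regression
from .ibr_model import IBRConfig, effect_summary, gelman_rubin, run_chains
from .landcover import CountyEraMap, harmonized_table, load_census
from .popgen import (
    allele_counts, diversity_table, filter_maf, filter_missing, folded_sfs,
    fst_matrix, impute_mode, load_genotypes, nucleotide_diversity,
)
from .resistance import geographic_distance_matrix, load_sites, lrt_matrix, write_matrix

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and model settings for one full run."""

    polygons: dict[int, str]           # era -> GeoJSON path
    census: str                        # census CSV (all eras)
    sites: str                         # sites CSV
    genotypes: str                     # VCF or genotype CSV
    eras: list[int]
    outdir: str
    genotype_format: str = "vcf"
    populations: str | None = None     # individual -> population CSV (VCF input)
    reference_era: int | None = None   # era whose polygons are the harmonization target
    harmonize_mode: str = "printed"
    maf_threshold: float = 0.05
    missing_threshold: float = 0.30
    impute_scope: str = "population"
    total_sites: int | None = None
    seed: int = 0
    ibr: IBRConfig = field(default_factory=IBRConfig)

    def __post_init__(self) -> None:
        if not self.eras:
            raise ValueError("eras must be nonempty")
        if self.reference_era is None:
            self.reference_era = max(self.eras)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ibr = IBRConfig(**raw.pop("ibr", {}))
        raw["polygons"] = {int(k): v for k, v in raw["polygons"].items()}
        raw["eras"] = [int(e) for e in raw["eras"]]
        return cls(ibr=ibr, **raw)

    def input_paths(self) -> list[str]:
        paths = [self.census, self.sites, self.genotypes, *self.polygons.values()]
        if self.populations:
            paths.append(self.populations)
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def run(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    for p in config.input_paths():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "started": _now(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in config.input_paths()},
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "ibr"
        },
        "ibr_config": dataclasses.asdict(config.ibr),
        "stages": [],
    }

    def finish_stage(name: str) -> None:
        manifest["stages"].append({"stage": name, "completed": _now()})
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "landcover"
    try:
        maps: dict[int, CountyEraMap] = {
            era: load_census(config.census, config.polygons[era], era)
            for era in config.eras
        }
        reference = maps[config.reference_era]
        for era in config.eras:
            tbl = harmonized_table(maps[era], reference, era, mode=config.harmonize_mode)
            tbl.to_csv(outdir / f"harmonized_{era}.csv", index=False)
        finish_stage(stage)

        stage = "resistance"
        sites = load_sites(config.sites)
        D = geographic_distance_matrix(sites, standardize=True)
        write_matrix(D, outdir / "distance.csv")
        E_list = []
        for era in config.eras:
            E = lrt_matrix(sites, maps[era], era, standardize=True)
            write_matrix(E, outdir / f"resistance_{era}.csv")
            E_list.append(E)
        finish_stage(stage)

        stage = "popgen"
        pops_map = None
        if config.populations:
            import pandas as pd

            pdf = pd.read_csv(config.populations, dtype=str)
            pops_map = dict(zip(pdf["individual_id"], pdf["population_label"]))
        g = load_genotypes(config.genotypes, format=config.genotype_format, populations=pops_map)
        g = filter_maf(g, config.maf_threshold)
        g = filter_missing(g, config.missing_threshold)
        g = impute_mode(g, scope=config.impute_scope)
        total_sites = config.total_sites or g.n_loci
        pop_order = [s.population_label for s in sites]
        fst = fst_matrix(g, sites_order=pop_order)
        # relabel rows/columns with site ids so fst aligns with D and E
        from .resistance import PairwiseMatrix

        fst = PairwiseMatrix(
            site_ids=[s.site_id for s in sites], values=fst.values, label="fst"
        )
        fst_frame = fst.to_frame()
        fst_frame.to_csv(outdir / "fst.csv", index_label="site_id")
        div = diversity_table(g, total_sites)
        div.to_csv(outdir / "diversity.csv", index=False)
        sfs_rows = []
        for pop in g.populations:
            sfs = folded_sfs(g, pop)
            for k, count in enumerate(sfs.bins):
                if k <= sfs.allele_number // 2:
                    sfs_rows.append({"population": pop, "minor_allele_count": k, "n_loci": int(count)})
        import pandas as pd

        pd.DataFrame(sfs_rows).to_csv(outdir / "folded_sfs.csv", index=False)
        counts = allele_counts(g)
        # counts rows must follow the site ordering used by D and E
        order = [counts.populations.index(p) for p in pop_order]
        counts.populations = [counts.populations[i] for i in order]
        counts.alt_count = counts.alt_count[order]
        counts.allele_number = counts.allele_number[order]
        finish_stage(stage)

        stage = "ibr"
        cfg = config.ibr
        per_era_posts = []
        for era in config.eras:
            era_cfg = dataclasses.replace(
                cfg, covariate_labels=[str(era)], seed=cfg.seed + era
            )
            posts = run_chains(counts, D, [E_list[config.eras.index(era)]], era_cfg)
            per_era_posts.extend(posts)
            rhat, upper = gelman_rubin([p.ratio(0)[p.retained()] for p in posts])
            logger.info("era %s: ratio R-hat %.3f (upper %.3f)", era, rhat, upper)
        all_cfg = dataclasses.replace(
            cfg, covariate_labels=[str(e) for e in config.eras], seed=cfg.seed + 1
        )
        all_posts = run_chains(counts, D, E_list, all_cfg)
        trace_rows = []
        for post in per_era_posts + all_posts:
            retained = post.retained()
            for k, lab in enumerate(post.covariate_labels):
                trace_rows.append(
                    {
                        "model": "per_era" if post in per_era_posts else "all_eras",
                        "era": lab,
                        "chain": post.chain_id,
                        "ratio_estimate": post.ratio_estimate(k),
                        "mean_log_posterior": float(post.log_posterior[retained].mean()),
                    }
                )
        pd.DataFrame(trace_rows).to_csv(outdir / "chain_estimates.csv", index=False)
        finish_stage(stage)

        stage = "effect_summary"
        labels = [str(e) for e in config.eras]
        if len(config.eras) >= 2:
            summary = effect_summary(per_era_posts, labels)
            summary.to_frame().to_csv(outdir / "effect_summary.csv", index=False)
            summary_all = effect_summary(all_posts, labels)
            summary_all.to_frame().to_csv(outdir / "effect_summary_all_eras.csv", index=False)
        else:
            summary = effect_summary(per_era_posts, labels[:1])
            summary.to_frame().to_csv(outdir / "effect_summary.csv", index=False)
        finish_stage(stage)

        stage = "association"
        assoc_rows = []
        for era, E in zip(config.eras, E_list):
            st1, st2 = residual_regression(fst, D, E)
            assoc_rows.append(
                {
                    "test": "fst_residual_vs_resistance",
                    "era": era,
                    "slope": st2.slope,
                    "p_value": st2.p_value,
                    "r_squared": st2.r_squared,
                    "stage1_slope": st1.slope,
                    "stage1_p": st1.p_value,
                }
            )
        pi = np.array(
            [nucleotide_diversity(g, s.population_label, total_sites) for s in sites]
        )
        fd = fst_vs_diversity(fst, pi)
        assoc_rows.append(
            {"test": "fst_vs_diversity", "era": "", "slope": fd.slope,
             "p_value": fd.p_value, "r_squared": fd.r_squared,
             "stage1_slope": np.nan, "stage1_p": np.nan}
        )
        for era in config.eras:
            cover = _site_cover(maps[era], sites, era)
            if np.ptp(cover) > 0:
                dr = diversity_regression(pi, cover, era_label=era)
                assoc_rows.append(
                    {"test": "diversity_vs_cover", "era": era, "slope": dr.slope,
                     "p_value": dr.p_value, "r_squared": dr.r_squared,
                     "stage1_slope": np.nan, "stage1_p": np.nan}
                )
        pd.DataFrame(assoc_rows).to_csv(outdir / "associations.csv", index=False)
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise StageError(stage, exc) from exc

    manifest["finished"] = _now()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def _site_cover(county_map: CountyEraMap, sites, era: int) -> np.ndarray:
    """Crop-cover proportion of the county containing each site (0 if none)."""
    out = np.zeros(len(sites))
    for i, s in enumerate(sites):
        for cid, geom in county_map.counties.items():
            if geom.covers(s.point):
                out[i] = county_map.proportion(era, cid)
                break
    return out


# ---------------------------------------------------------------------------
# CLI

@click.group(help="Historical landscape genetics pipeline.")
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
def main(verbose: bool) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        stream=sys.stderr,
    )


@main.command()
@click.argument("scenario", type=click.Choice(["null", "ibr_strong", "era_contrast"]))
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
def simulate(scenario: str, outdir: str, seed: int) -> None:
    """Write a synthetic fixture bundle."""
    from .synthetic_data import make_fixture

    path = make_fixture(scenario, outdir, seed=seed)
    click.echo(f"fixture written to {path}")


@main.command("landcover")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def landcover_cmd(config_path: str) -> None:
    """Harmonize census eras onto reference county boundaries."""
    config = PipelineConfig.from_yaml(config_path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = load_census(config.census, config.polygons[config.reference_era], config.reference_era)
    for era in config.eras:
        m = load_census(config.census, config.polygons[era], era)
        tbl = harmonized_table(m, reference, era, mode=config.harmonize_mode)
        tbl.to_csv(outdir / f"harmonized_{era}.csv", index=False)
    click.echo(f"harmonized tables written to {outdir}")


@main.command("resistance")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def resistance_cmd(config_path: str) -> None:
    """Write distance and per-era resistance matrices."""
    config = PipelineConfig.from_yaml(config_path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = load_sites(config.sites)
    write_matrix(geographic_distance_matrix(sites), outdir / "distance.csv")
    for era in config.eras:
        m = load_census(config.census, config.polygons[era], era)
        write_matrix(lrt_matrix(sites, m, era), outdir / f"resistance_{era}.csv")
    click.echo(f"matrices written to {outdir}")


@main.command("popgen")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def popgen_cmd(config_path: str) -> None:
    """Filters, imputation and summary statistics."""
    config = PipelineConfig.from_yaml(config_path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pops_map = None
    if config.populations:
        import pandas as pd

        pdf = pd.read_csv(config.populations, dtype=str)
        pops_map = dict(zip(pdf["individual_id"], pdf["population_label"]))
    g = load_genotypes(config.genotypes, format=config.genotype_format, populations=pops_map)
    g = impute_mode(filter_missing(filter_maf(g, config.maf_threshold), config.missing_threshold),
                    scope=config.impute_scope)
    total = config.total_sites or g.n_loci
    fst_matrix(g).to_frame().to_csv(outdir / "fst.csv", index_label="site_id")
    diversity_table(g, total).to_csv(outdir / "diversity.csv", index=False)
    click.echo(f"popgen outputs written to {outdir}")


@main.command("ibr")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None, help="Override config seed.")
def ibr_cmd(config_path: str, seed: int | None) -> None:
    """Per-era and all-era covariance models (runs the full pipeline)."""
    config = PipelineConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
        config.ibr.seed = seed
    outdir = run(config)
    click.echo(f"run complete: {outdir}")


@main.command("associate")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def associate_cmd(config_path: str) -> None:
    """Regression battery (runs the full pipeline)."""
    outdir = run(PipelineConfig.from_yaml(config_path))
    click.echo(f"run complete: {outdir}")


@main.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None, help="Override config seed.")
@click.option("--outdir", type=click.Path(), default=None, help="Override output directory.")
def run_all(config_path: str, seed: int | None, outdir: str | None) -> None:
    """Full analysis: landcover through associations."""
    config = PipelineConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
        config.ibr.seed = seed
    if outdir is not None:
        config.outdir = outdir
    path = run(config)
    click.echo(f"run complete: {path}")


if __name__ == "__main__":
    main()
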