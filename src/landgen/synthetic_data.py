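"""Synthetic landscapes, census histories, sites and genotypes.

The generator emulates the statistical structure the analysis assumes: a
rectangular grid of counties (axis-aligned so transect segment lengths
have closed forms and LRT oracles are exact), per-era crop-cover
patterns, sampling sites in county interiors, and SNP genotypes whose
allele-frequency covariance decays with a weighted sum of geographic
distance and era-specific landscape resistance:

    freq_l ~ TruncNormal_[0,1]( mu_l, mu_l (1 - mu_l) * Omega ),
    Omega[i,j] = (1/alpha0) exp(-(alphaD D + sum_k alphaE_k E_k)),

with genotypes drawn binomial(2, q) around a per-population
beta-perturbed frequency q ~ Beta(freq*phi, (1-freq)*phi) — the
beta-binomial observation layer of the inference model — and missing
calls injected at a configurable rate.

Default study conditions mirror a regional GBS survey of an insect pest:
8 populations of 12 diploids each, ~1,000 biallelic SNPs, three census
eras, a true resistance-to-distance effect ratio of 10 in the "strong"
scenario, mild overdispersion (phi = 100) and 2% missing calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping

from .landcover import CountyEraMap
from .popgen import MISSING, AlleleCountTable, GenotypeMatrix, allele_counts
from .resistance import PairwiseMatrix, SiteSample

logger = logging.getLogger(__name__)

#: planar offset (meters) so toy coordinates never look like lon/lat degrees
DEFAULT_ORIGIN = (500_000.0, 5_000_000.0)


@dataclass
class SimulationSpec:
    """Everything that defines one synthetic study.

    ``cover_models`` maps era -> cover pattern, one of
    ``{"kind": "uniform", "p": ...}``,
    ``{"kind": "gradient", "axis": "x"|"y", "p_min": ..., "p_max": ...}``,
    ``{"kind": "patch", "rows": (r0, r1), "cols": (c0, c1), "p_in": ..., "p_out": ...}``
    (row/col ranges are half-open).  ``true_alpha`` holds the generative
    parameters (alphaD, alphaE per era entering the covariance, alpha0,
    alpha2).
    """

    grid: tuple[int, int] = (6, 6)
    county_size: float = 10_000.0
    origin: tuple[float, float] = DEFAULT_ORIGIN
    eras: list[int] = field(default_factory=lambda: [1860, 1910, 2012])
    cover_models: dict[int, dict] = field(default_factory=dict)
    n_sites: int = 8
    inds_per_pop: int = 12
    n_loci: int = 1000
    alpha_d: float = 0.05
    alpha_e: dict[int, float] = field(default_factory=dict)
    alpha_0: float = 20.0
    alpha_2: float = 1.0
    dispersion: float = 100.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.cover_models:
            self.cover_models = {era: {"kind": "uniform", "p": 0.2} for era in self.eras}
        if not self.alpha_e:
            self.alpha_e = {era: 0.0 for era in self.eras}


def _cover_value(model: dict, r: int, c: int, rows: int, cols: int) -> float:
    kind = model["kind"]
    if kind == "uniform":
        return float(model["p"])
    if kind == "gradient":
        frac = c / max(cols - 1, 1) if model.get("axis", "x") == "x" else r / max(rows - 1, 1)
        return float(model["p_min"] + (model["p_max"] - model["p_min"]) * frac)
    if kind == "patch":
        r0, r1 = model["rows"]
        c0, c1 = model["cols"]
        inside = r0 <= r < r1 and c0 <= c < c1
        return float(model["p_in"] if inside else model["p_out"])
    raise ValueError(f"unknown cover model kind {kind!r}")


def make_landscape(spec: SimulationSpec) -> tuple[CountyEraMap, list[SiteSample]]:
    """Rectangular county grid with per-era cover, plus sampling sites.

    Sites are placed at the centers of distinct, seeded-randomly chosen
    counties; each site defines one population (P1, P2, ...).
    """
    rows, cols = spec.grid
    if spec.n_sites > rows * cols:
        raise ValueError(f"n_sites ({spec.n_sites}) exceeds county count ({rows * cols})")
    ox, oy = spec.origin
    s = spec.county_size
    counties = {}
    for r in range(rows):
        for c in range(cols):
            cid = f"C{r}_{c}"
            counties[cid] = box(ox + c * s, oy + r * s, ox + (c + 1) * s, oy + (r + 1) * s)
    proportions = {
        era: {
            f"C{r}_{c}": _cover_value(spec.cover_models[era], r, c, rows, cols)
            for r in range(rows)
            for c in range(cols)
        }
        for era in spec.eras
    }
    county_map = CountyEraMap(counties=counties, proportions=proportions)

    rng = np.random.default_rng(spec.seed)
    cells = rng.choice(rows * cols, size=spec.n_sites, replace=False)
    sites = []
    for k, cell in enumerate(sorted(int(v) for v in cells)):
        r, c = divmod(cell, cols)
        sites.append(
            SiteSample(
                site_id=f"S{k + 1}",
                x=ox + (c + 0.5) * s,
                y=oy + (r + 0.5) * s,
                population_label=f"P{k + 1}",
            )
        )
    return county_map, sites


def simulate_frequencies(
    spec: SimulationSpec, D: PairwiseMatrix, E_list: list[PairwiseMatrix]
) -> np.ndarray:
    """Latent population-by-locus allele frequencies under the covariance model.

    Per locus: mu_l ~ Uniform(0.05, 0.95); population frequencies are
    multivariate normal with mean mu_l and covariance mu_l(1-mu_l)*Omega,
    truncated to [0, 1] by rejection (up to 100 redraws per locus, then
    clipping with a log message).
    """
    from .ibr_model import build_covariance

    alpha_e = [spec.alpha_e[era] for era in spec.eras if era in spec.alpha_e]
    if len(alpha_e) != len(E_list):
        alpha_e = list(spec.alpha_e.values())[: len(E_list)]
    omega = build_covariance(D, E_list, spec.alpha_0, spec.alpha_d, alpha_e, spec.alpha_2)
    P = omega.shape[0]
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        logger.warning("Omega not positive definite; jitter added")
        chol = np.linalg.cholesky(omega + 1e-8 * np.eye(P))

    rng = np.random.default_rng(spec.seed + 1)
    mu = rng.uniform(0.05, 0.95, size=spec.n_loci)
    freqs = np.empty((P, spec.n_loci))
    pending = np.ones(spec.n_loci, dtype=bool)
    for _ in range(100):
        if not pending.any():
            break
        idx = np.flatnonzero(pending)
        z = rng.standard_normal((P, idx.size))
        draw = mu[idx] + np.sqrt(mu[idx] * (1 - mu[idx])) * (chol @ z)
        ok = ((draw >= 0.0) & (draw <= 1.0)).all(axis=0)
        freqs[:, idx[ok]] = draw[:, ok]
        pending[idx[ok]] = False
    if pending.any():
        logger.info(
            "simulate_frequencies: clipped %d locus/loci after 100 rejection tries",
            int(pending.sum()),
        )
        idx = np.flatnonzero(pending)
        z = rng.standard_normal((P, idx.size))
        draw = mu[idx] + np.sqrt(mu[idx] * (1 - mu[idx])) * (chol @ z)
        freqs[:, idx] = np.clip(draw, 0.0, 1.0)
    return freqs


def sample_genotypes(
    freqs: np.ndarray, spec: SimulationSpec
) -> tuple[GenotypeMatrix, AlleleCountTable]:
    """Diploid genotypes around beta-perturbed population frequencies.

    One beta draw per (population, locus) — shared by all individuals of
    the population, so the population's allele total is marginally
    beta-binomial — then per-individual binomial(2, q) genotypes, with
    missing calls injected at ``spec.missing_rate``.
    """
    P, L = freqs.shape
    rng = np.random.default_rng(spec.seed + 2)
    phi = spec.dispersion
    interior = (freqs > 0) & (freqs < 1)
    q = freqs.copy()
    a = np.where(interior, freqs * phi, 1.0)
    b = np.where(interior, (1 - freqs) * phi, 1.0)
    beta = rng.beta(a, b)
    q[interior] = beta[interior]

    n = spec.inds_per_pop
    calls = np.empty((P * n, L), dtype=np.int8)
    ids, pops = [], []
    for k in range(P):
        calls[k * n : (k + 1) * n] = rng.binomial(2, q[k], size=(n, L))
        ids.extend(f"P{k + 1}_I{i + 1}" for i in range(n))
        pops.extend([f"P{k + 1}"] * n)
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING
    g = GenotypeMatrix(
        individual_ids=ids,
        population_labels=pops,
        locus_ids=[f"L{l + 1}" for l in range(L)],
        calls=calls,
    )
    return g, allele_counts(g)


# ---------------------------------------------------------------------------
# fixture bundles

def _scenario_spec(name: str, seed: int) -> SimulationSpec:
    common = dict(
        grid=(6, 6),
        county_size=10_000.0,
        n_sites=8,
        inds_per_pop=12,
        n_loci=500,
        alpha_0=20.0,
        alpha_2=1.0,
        dispersion=100.0,
        missing_rate=0.02,
        seed=seed,
    )
    gradient = {"kind": "gradient", "axis": "x", "p_min": 0.02, "p_max": 0.6}
    if name == "null":
        return SimulationSpec(
            eras=[2012], cover_models={2012: gradient},
            alpha_d=0.05, alpha_e={2012: 0.0}, **common,
        )
    if name == "ibr_strong":
        return SimulationSpec(
            eras=[2012], cover_models={2012: gradient},
            alpha_d=0.05, alpha_e={2012: 0.5}, **common,
        )
    if name == "era_contrast":
        return SimulationSpec(
            eras=[1860, 1910, 2012],
            cover_models={
                1860: {"kind": "gradient", "axis": "x", "p_min": 0.02, "p_max": 0.6},
                1910: {"kind": "gradient", "axis": "y", "p_min": 0.02, "p_max": 0.6},
                2012: {"kind": "patch", "rows": (0, 3), "cols": (0, 3),
                       "p_in": 0.6, "p_out": 0.02},
            },
            alpha_d=0.05,
            alpha_e={1860: 0.0, 1910: 0.0, 2012: 0.5},
            **common,
        )
    raise ValueError(f"unknown fixture name {name!r}; use null | ibr_strong | era_contrast")


def simulate_study(spec: SimulationSpec):
    """Run the full generative model; returns (county_map, sites, D, E_list, freqs, genotypes, counts).

    Covariates are standardized pairwise matrices, exactly what the
    inference model consumes; genotypes are generated from the eras whose
    alpha_e is nonzero (plus geographic distance).
    """
    from .resistance import geographic_distance_matrix, lrt_matrix

    county_map, sites = make_landscape(spec)
    D = geographic_distance_matrix(sites, standardize=True)
    E_list = [lrt_matrix(sites, county_map, era, standardize=True) for era in spec.eras]
    freqs = simulate_frequencies(spec, D, E_list)
    g, counts = sample_genotypes(freqs, spec)
    return county_map, sites, D, E_list, freqs, g, counts


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal biallelic VCF 4.2 (GT only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={g.n_loci + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        for l, lid in enumerate(g.locus_ids):
            gts = "\t".join(gt_str[int(c)] for c in g.calls[:, l])
            fh.write(f"1\t{l + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_geojson(county_map: CountyEraMap, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"county_id": cid},
            "geometry": mapping(geom),
        }
        for cid, geom in sorted(county_map.counties.items())
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def make_fixture(name: str, outdir, seed: int = 0) -> Path:
    """Write a canned scenario bundle (GeoJSON + CSVs + VCF + manifest).

    Scenarios: ``null`` (no landscape effect), ``ibr_strong`` (one era,
    true alphaE/alphaD = 10), ``era_contrast`` (three eras, genotypes
    driven by the contemporary era's resistance only).
    """
    spec = _scenario_spec(name, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    county_map, sites, D, E_list, freqs, g, counts = simulate_study(spec)

    write_geojson(county_map, outdir / "counties.geojson")
    with open(outdir / "census.csv", "w") as fh:
        fh.write("county_id,year,potato_area,county_area\n")
        for era in spec.eras:
            for cid in sorted(county_map.counties):
                area = county_map.area(cid)
                fh.write(f"{cid},{era},{county_map.proportion(era, cid) * area},{area}\n")
    with open(outdir / "sites.csv", "w") as fh:
        fh.write("site_id,x,y,population_label\n")
        for s in sites:
            fh.write(f"{s.site_id},{s.x},{s.y},{s.population_label}\n")
    with open(outdir / "populations.csv", "w") as fh:
        fh.write("individual_id,population_label\n")
        for iid, pop in zip(g.individual_ids, g.population_labels):
            fh.write(f"{iid},{pop}\n")
    write_vcf(g, outdir / "genotypes.vcf")
    manifest = {
        "scenario": name,
        "seed": seed,
        "eras": spec.eras,
        "true_alpha": {
            "alpha_d": spec.alpha_d,
            "alpha_e": {str(k): v for k, v in spec.alpha_e.items()},
            "alpha_0": spec.alpha_0,
            "alpha_2": spec.alpha_2,
        },
        "n_sites": spec.n_sites,
        "inds_per_pop": spec.inds_per_pop,
        "n_loci": spec.n_loci,
        "dispersion": spec.dispersion,
        "missing_rate": spec.missing_rate,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
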