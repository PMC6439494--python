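"""Landscape resistance to transmission (LRT) between sampling sites.

LRT treats a host crop as a conduit to dispersal: the straight line
("shortest path line") between two sites is cut into segments by the
county polygons it crosses, and resistance is the inverse of the
path-length-weighted mean crop proportion along the line,

    LRT = 1 / sum_i (Z_i * L_i / L_T)

where ``Z_i`` is the crop proportion of county *i* for the chosen census
era, ``L_i`` the length of the transect segment inside county *i*, and
``L_T`` the total transect length.  LRT is 1 when the whole path crosses
saturated crop cover, grows as cover thins, and is +inf when no crop
lies anywhere along the path.  Portions of a transect covered by no
county (water, map edge) contribute Z = 0 — resistance due to the
absence of the crop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .landcover import CountyEraMap, ValidationError

logger = logging.getLogger(__name__)

#: county_id used for transect portions covered by no county polygon
NO_COUNTY = None


class DegeneratePathError(ValueError):
    """Both transect endpoints coincide."""


@dataclass(frozen=True)
class SiteSample:
    """A genotyped sampling site in planar meter coordinates."""

    site_id: str
    x: float
    y: float
    population_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"site {self.site_id!r}: non-finite coordinates")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class PathSegments:
    """Ordered decomposition of a transect by county.

    ``segments`` is an ordered list of (county_id | None, length_m) along
    the path; lengths sum to ``total_length`` (the Euclidean distance
    between the endpoints).
    """

    segments: list[tuple[str | None, float]]
    total_length: float

    def __post_init__(self) -> None:
        if any(L < 0 for _, L in self.segments):
            raise ValidationError("negative segment length")
        s = sum(L for _, L in self.segments)
        if abs(s - self.total_length) > 1e-6 * max(self.total_length, 1.0):
            raise ValidationError(
                f"segment lengths sum to {s}, expected {self.total_length}"
            )


@dataclass
class PairwiseMatrix:
    """Symmetric site-by-site matrix (distance, resistance:era, or fst)."""

    site_ids: list[str]
    values: np.ndarray
    label: str
    standardized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        finite = np.isfinite(v)
        if not np.allclose(np.where(finite, v, 0.0), np.where(finite.T, v.T, 0.0)):
            raise ValidationError("matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def reorder(self, site_ids: list[str]) -> "PairwiseMatrix":
        idx = [self.site_ids.index(s) for s in site_ids]
        return PairwiseMatrix(
            site_ids=list(site_ids),
            values=self.values[np.ix_(idx, idx)],
            label=self.label,
            standardized=self.standardized,
        )


def segment_path(a: SiteSample, b: SiteSample, county_map: CountyEraMap) -> PathSegments:
    """Cut the straight line a→b into per-county segments.

    Intersections are resolved on the 1-D parameter of the line: each
    county contributes the interval(s) of the line inside it; elementary
    intervals covered by more than one county (a line lying on a shared
    boundary) are assigned to the lexicographically smallest county_id,
    and uncovered intervals are reported with county_id ``None``.
    """
    if a.x == b.x and a.y == b.y:
        raise DegeneratePathError(f"sites {a.site_id!r} and {b.site_id!r} coincide")
    line = LineString([(a.x, a.y), (b.x, b.y)])
    total = line.length

    # collect coverage intervals [t0, t1] (meters along the line) per county
    intervals: list[tuple[float, float, str]] = []
    for cid in sorted(county_map.counties):
        inter = line.intersection(county_map.counties[cid])
        if inter.is_empty:
            continue
        parts = getattr(inter, "geoms", [inter])
        for part in parts:
            if part.geom_type != "LineString" or part.length == 0:
                continue  # point touches carry no length
            coords = list(part.coords)
            ts = [line.project(Point(c)) for c in coords]
            t0, t1 = min(ts), max(ts)
            if t1 > t0:
                intervals.append((t0, t1, cid))

    # sweep over elementary intervals between all breakpoints
    cuts = sorted({0.0, total, *(t for t0, t1, _ in intervals for t in (t0, t1))})
    raw: list[tuple[str | None, float]] = []
    tie_logged = False
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        covering = sorted(c for t0, t1, c in intervals if t0 <= mid <= t1)
        if not covering:
            raw.append((NO_COUNTY, hi - lo))
        else:
            if len(covering) > 1 and not tie_logged:
                logger.info(
                    "transect %s-%s lies on a shared boundary; assigned to %r "
                    "(lexicographic tie-break)", a.site_id, b.site_id, covering[0],
                )
                tie_logged = True
            raw.append((covering[0], hi - lo))

    # merge consecutive segments in the same county
    merged: list[tuple[str | None, float]] = []
    for cid, L in raw:
        if merged and merged[-1][0] == cid:
            merged[-1] = (cid, merged[-1][1] + L)
        else:
            merged.append((cid, L))
    return PathSegments(segments=merged, total_length=total)


def lrt_pair(a: SiteSample, b: SiteSample, county_map: CountyEraMap, era: int) -> float:
    """LRT between two sites for one census era (may be +inf).

    Exactly symmetric in (a, b): the transect is traversed from the
    endpoint with the smaller (x, y) so float summation order cannot
    differ between the two call directions.
    """
    if era not in county_map.proportions:
        raise ValidationError(f"era {era} absent from county map")
    if (b.x, b.y) < (a.x, a.y):
        a, b = b, a
    segs = segment_path(a, b, county_map)
    denom = 0.0
    for cid, L in segs.segments:
        z = 0.0 if cid is NO_COUNTY else county_map.proportion(era, cid)
        denom += z * L / segs.total_length
    if denom == 0.0:
        logger.warning(
            "LRT(%s, %s, era %d) is infinite: no crop cover anywhere along the path",
            a.site_id, b.site_id, era,
        )
        return math.inf
    return 1.0 / denom


def _standardize(values: np.ndarray, label: str) -> np.ndarray:
    """Divide off-diagonal entries by the sample SD of the upper triangle."""
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    tri = values[iu]
    finite = tri[np.isfinite(tri)]
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    if sd == 0.0:
        raise ValidationError(
            f"{label}: zero SD over pairs; standardization impossible "
            "(use standardize=False)"
        )
    out = values / sd
    np.fill_diagonal(out, np.diag(values))
    return out


def lrt_matrix(
    sites: list[SiteSample], county_map: CountyEraMap, era: int, standardize: bool = True
) -> PairwiseMatrix:
    """Pairwise LRT matrix for one era; optionally SD-standardized.

    Infinite entries (pairs with no crop anywhere along the transect)
    propagate and trigger a warning; see
    :func:`landgen.ibr_model.prepare_covariates` for the downstream
    replacement policy.
    """
    n = len(sites)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = lrt_pair(sites[i], sites[j], county_map, era)
    if np.isinf(vals).any():
        logger.warning("lrt_matrix era %d: %d infinite pair(s)", era, int(np.isinf(vals).sum()) // 2)
    if standardize:
        if n < 3:
            raise ValidationError("standardization needs >= 3 sites")
        vals = _standardize(vals, f"resistance:{era}")
    return PairwiseMatrix(
        site_ids=[s.site_id for s in sites],
        values=vals,
        label=f"resistance:{era}",
        standardized=standardize,
    )


def geographic_distance_matrix(
    sites: list[SiteSample], standardize: bool = True
) -> PairwiseMatrix:
    """Pairwise Euclidean distances in the planar projection."""
    if len(sites) < 2:
        raise ValidationError("need >= 2 sites")
    xy = np.array([(s.x, s.y) for s in sites])
    diff = xy[:, None, :] - xy[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    n = len(sites)
    iu = np.triu_indices(n, k=1)
    if (vals[iu] == 0).any():
        logger.warning("duplicate site coordinates: some pairwise distances are 0")
    if standardize:
        vals = _standardize(vals, "distance")
    return PairwiseMatrix(
        site_ids=[s.site_id for s in sites],
        values=vals,
        label="distance",
        standardized=standardize,
    )


def load_sites(csv_path) -> list[SiteSample]:
    """Read a sites CSV (site_id, x, y, population_label)."""
    df = pd.read_csv(csv_path, dtype={"site_id": str, "population_label": str})
    required = {"site_id", "x", "y", "population_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{csv_path}: missing columns {sorted(missing)}")
    sites = [
        SiteSample(str(r.site_id), float(r.x), float(r.y), str(r.population_label))
        for r in df.itertuples(index=False)
    ]
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{csv_path}: duplicate site_id values")
    return sites


def write_matrix(matrix: PairwiseMatrix, path) -> None:
    """Write a square CSV with site_id header row and column."""
    matrix.to_frame().to_csv(path, index_label="site_id")
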