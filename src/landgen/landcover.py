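"""County-level crop-cover censuses on changing county boundaries.

Agricultural censuses report crop area per county, but county boundaries
shift between census eras.  Before land cover can be compared across eras,
historic county values must be re-expressed on a fixed reference (modern)
set of county polygons.  This module loads census tables, converts crop
area to the proportion of county area (so that large and small counties
are comparable), and harmonizes historic values onto reference boundaries
by polygon overlap:

    value(R) = sum_i  a_i * p_i

where the sum runs over historic counties *i* intersecting reference
county *R*, ``p_i`` is the proportion of county *i* in the crop, and
``a_i = area(i ∩ R) / area(i)`` is the fraction of county *i* that
overlaps *R*.  This overlap-sum is reproduced verbatim as the default
("printed") mode; note it is not an area-weighted mean — merging two full
historic counties into one reference county yields p1 + p2.  A "weighted"
mode computing ``sum_i area(i ∩ R) * p_i / area(R)`` (a true areal
interpolation, bounded in [0, 1]) is available via ``mode="weighted"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

HARMONIZE_MODES = ("printed", "weighted")


class FormatError(ValueError):
    """Input file does not conform to the documented layout."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


@dataclass
class CensusRecord:
    """One county-year row of a crop census.

    ``potato_area`` and ``county_area`` must be in the same (arbitrary)
    areal units; only their ratio is used downstream.
    """

    county_id: str
    year: int
    potato_area: float
    county_area: float

    def __post_init__(self) -> None:
        if self.county_area <= 0:
            raise ValidationError(
                f"county {self.county_id!r}: county_area must be positive "
                f"(got {self.county_area})"
            )
        if self.potato_area < 0:
            raise ValidationError(
                f"county {self.county_id!r}: potato_area must be nonnegative "
                f"(got {self.potato_area})"
            )
        if self.potato_area > self.county_area:
            raise ValidationError(
                f"county {self.county_id!r}: potato_area ({self.potato_area}) "
                f"exceeds county_area ({self.county_area})"
            )

    @property
    def proportion(self) -> float:
        return self.potato_area / self.county_area


@dataclass
class CountyEraMap:
    """County polygons plus per-era crop proportions.

    ``counties`` maps county_id -> shapely polygon in a planar projection
    with meter units.  ``proportions`` maps era -> county_id -> proportion
    of county area in the crop.
    """

    counties: dict[str, BaseGeometry]
    proportions: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, geom in self.counties.items():
            if geom.area <= 0:
                raise ValidationError(f"county {cid!r}: polygon area must be > 0")
        for era, props in self.proportions.items():
            for cid, p in props.items():
                if cid not in self.counties:
                    raise ValidationError(
                        f"era {era}: proportion given for unknown county {cid!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"era {era}, county {cid!r}: proportion {p} outside [0, 1]"
                    )

    @property
    def eras(self) -> list[int]:
        return sorted(self.proportions)

    def area(self, county_id: str) -> float:
        return self.counties[county_id].area

    def proportion(self, era: int, county_id: str) -> float:
        return self.proportions[era].get(county_id, 0.0)

    def check_no_overlap(self, rel_tol: float = 1e-9) -> None:
        """Raise if any two county polygons overlap materially.

        Overlap is measured as intersection area over union area; shared
        boundaries (zero-area intersections) are fine.
        """
        ids = sorted(self.counties)
        geoms = [self.counties[c] for c in ids]
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                j = int(j)
                if j <= i:
                    continue
                inter = g.intersection(geoms[j]).area
                if inter <= 0:
                    continue
                union = g.union(geoms[j]).area
                if inter / union >= rel_tol:
                    raise ValidationError(
                        f"counties {ids[i]!r} and {ids[j]!r} overlap "
                        f"(intersection/union = {inter / union:.3g})"
                    )


def _validate_planar(counties: dict[str, BaseGeometry]) -> None:
    """Reject coordinate sets that look like lon/lat degrees.

    The pipeline never reprojects; all geometry must be in a planar
    projection with meter units.  If every vertex satisfies |x| <= 360 and
    |y| <= 90 the polygons are indistinguishable from geographic
    coordinates and are rejected with an explanatory error.
    """
    xmax = ymax = 0.0
    for geom in counties.values():
        minx, miny, maxx, maxy = geom.bounds
        xmax = max(xmax, abs(minx), abs(maxx))
        ymax = max(ymax, abs(miny), abs(maxy))
    if xmax <= 360.0 and ymax <= 90.0:
        raise ValidationError(
            "polygon coordinates all lie within |x| <= 360, |y| <= 90; this "
            "looks like unprojected lon/lat. Supply geometry in a planar "
            "projection with meter units (the pipeline never reprojects)."
        )


def _repair(geom: BaseGeometry, county_id: str) -> BaseGeometry:
    if not geom.is_valid:
        logger.warning("county %r: invalid polygon repaired by zero-width buffer", county_id)
        geom = geom.buffer(0)
    return geom


def load_polygons(polygons_path) -> dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection keyed by the 'county_id' property."""
    with open(polygons_path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{polygons_path}: expected a GeoJSON FeatureCollection")
    counties: dict[str, BaseGeometry] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "county_id" not in props:
            raise FormatError(f"{polygons_path}: feature missing 'county_id' property")
        cid = str(props["county_id"])
        counties[cid] = _repair(shape(feat["geometry"]), cid)
    if not counties:
        raise FormatError(f"{polygons_path}: no features found")
    _validate_planar(counties)
    return counties


def load_census(csv_path, polygons_path, era: int) -> CountyEraMap:
    """Load one census era onto its county polygons.

    The CSV must have columns county_id, year, potato_area, county_area;
    rows are filtered to ``year == era``.  Counties present in the polygon
    file but absent from the census get proportion 0 with a warning.
    """
    counties = load_polygons(polygons_path)
    df = pd.read_csv(csv_path, dtype={"county_id": str})
    required = {"county_id", "year", "potato_area", "county_area"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing columns {sorted(missing)}")
    df = df[df["year"] == era]
    props: dict[str, float] = {}
    for row in df.itertuples(index=False):
        rec = CensusRecord(
            county_id=str(row.county_id),
            year=int(row.year),
            potato_area=float(row.potato_area),
            county_area=float(row.county_area),
        )
        if rec.county_id not in counties:
            logger.warning(
                "census %s era %d: county %r has no polygon; row ignored",
                csv_path, era, rec.county_id,
            )
            continue
        props[rec.county_id] = rec.proportion
    for cid in counties:
        if cid not in props:
            logger.warning(
                "census %s era %d: county %r absent from census; proportion set to 0",
                csv_path, era, cid,
            )
            props[cid] = 0.0
    return CountyEraMap(counties=counties, proportions={era: props})


def harmonize(
    historic: CountyEraMap,
    reference: CountyEraMap,
    era: int,
    mode: str = "printed",
) -> dict[str, float]:
    """Re-express one era's county proportions on reference boundaries.

    "printed" mode evaluates the overlap sum sum_i a_i * p_i with
    a_i = area(i ∩ R)/area(i); raw sums are reported and values > 1 are
    logged.  "weighted" mode computes the area-weighted mean
    sum_i area(i ∩ R) * p_i / area(R), clipped to [0, 1].
    """
    if mode not in HARMONIZE_MODES:
        raise ValueError(f"mode must be one of {HARMONIZE_MODES}, got {mode!r}")
    if era not in historic.proportions:
        raise ValidationError(f"era {era} absent from historic map")
    props = historic.proportions[era]

    hist_ids = sorted(historic.counties)
    hist_geoms = [historic.counties[c] for c in hist_ids]
    tree = STRtree(hist_geoms)

    out: dict[str, float] = {}
    for rid in sorted(reference.counties):
        rgeom = reference.counties[rid]
        total = 0.0
        for j in tree.query(rgeom):
            hid = hist_ids[int(j)]
            hgeom = hist_geoms[int(j)]
            inter = hgeom.intersection(rgeom).area
            if inter <= 0:
                continue
            p = props.get(hid, 0.0)
            if mode == "printed":
                total += (inter / hgeom.area) * p
            else:
                total += inter * p
        if mode == "weighted":
            total /= rgeom.area
            total = min(max(total, 0.0), 1.0)
        elif total > 1.0:
            logger.warning(
                "harmonize era %d: reference county %r got printed-mode value "
                "%.6g > 1 (overlap sum is not a weighted mean)", era, rid, total,
            )
        out[rid] = total
    return out


def harmonized_table(
    historic: CountyEraMap, reference: CountyEraMap, era: int, mode: str = "printed"
) -> pd.DataFrame:
    """Harmonize and return a tidy table (reference_county_id, era, value, mode)."""
    values = harmonize(historic, reference, era, mode=mode)
    return pd.DataFrame(
        {
            "reference_county_id": list(values),
            "era": era,
            "value": list(values.values()),
            "mode": mode,
        }
    )


def potato_timeseries(maps: list[CountyEraMap], region_county_ids: set[str]) -> pd.Series:
    """Total crop area per era over a set of counties.

    Returns a Series indexed by era with sum over counties of
    proportion * county polygon area (same units as the polygon areas).
    """
    region = sorted(region_county_ids)
    if not region:
        return pd.Series(dtype=float, name="potato_area")
    totals: dict[int, float] = {}
    for m in maps:
        unknown = [c for c in region if c not in m.counties]
        if unknown:
            raise ValidationError(f"unknown county ids in region set: {unknown}")
        for era in m.proportions:
            totals[era] = sum(m.proportion(era, c) * m.area(c) for c in region)
    return pd.Series(totals, name="potato_area").sort_index()
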