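import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from landgen.landcover import CountyEraMap, ValidationError
from landgen.resistance import (
    DegeneratePathError,
    PairwiseMatrix,
    SiteSample,
    geographic_distance_matrix,
    lrt_matrix,
    lrt_pair,
    segment_path,
)

from _oracles import mc_lrt
from conftest import OX, OY, strip_map


class TestSegmentPath:
    def test_single_county_one_segment(self, site_pair):
        a, b = site_pair
        m = strip_map([1000], [0.3])
        segs = segment_path(a, b, m)
        assert segs.segments == [("C1", pytest.approx(1000.0))]
        assert segs.total_length == pytest.approx(1000.0)

    def test_two_abutting_counties_split_at_midpoint(self, site_pair):
        a, b = site_pair
        m = strip_map([500, 500], [0.3, 0.1])
        segs = segment_path(a, b, m)
        assert [c for c, _ in segs.segments] == ["C1", "C2"]
        for _, L in segs.segments:
            assert L == pytest.approx(500.0)

    def test_uncovered_gap_reported_as_none(self):
        m = CountyEraMap(
            counties={"C1": box(OX, OY, OX + 400, OY + 1000)},
            proportions={2012: {"C1": 0.5}},
        )
        a = SiteSample("A", OX, OY + 500, "P")
        b = SiteSample("B", OX + 1000, OY + 500, "P")
        segs = segment_path(a, b, m)
        assert segs.segments == [("C1", pytest.approx(400.0)), (None, pytest.approx(600.0))]

    def test_identical_sites_raise(self):
        a = SiteSample("A", OX, OY, "P")
        b = SiteSample("B", OX, OY, "P")
        with pytest.raises(DegeneratePathError):
            segment_path(a, b, strip_map([1000], [0.3]))

    def test_three_county_strip_matches_point_classification_oracle(self):
        m = strip_map([300, 450, 250], [0.1, 0.5, 0.2])
        a = SiteSample("A", OX + 13.0, OY + 220.0, "P")
        b = SiteSample("B", OX + 987.0, OY + 730.0, "P")
        segs = segment_path(a, b, m)
        total = math.hypot(b.x - a.x, b.y - a.y)
        assert segs.total_length == pytest.approx(total)
        # oracle: classify 1e5 points along the line per county
        ts = (np.arange(100_000) + 0.5) / 100_000
        xs, ys = a.x + ts * (b.x - a.x), a.y + ts * (b.y - a.y)
        from shapely import contains_xy

        for cid, length in segs.segments:
            frac = contains_xy(m.counties[cid], xs, ys).mean()
            assert length == pytest.approx(frac * total, rel=1e-3)


class TestLrtPair:
    def test_uniform_cover_is_inverse_proportion(self, site_pair):
        a, b = site_pair
        assert lrt_pair(a, b, strip_map([1000], [0.25]), 2012) == pytest.approx(4.0)

    def test_full_cover_is_minimum_resistance(self, site_pair):
        a, b = site_pair
        assert lrt_pair(a, b, strip_map([1000], [1.0]), 2012) == pytest.approx(1.0)

    def test_two_equal_segments_harmonic_form(self, site_pair):
        a, b = site_pair
        m = strip_map([500, 500], [0.2, 0.4])
        assert lrt_pair(a, b, m, 2012) == pytest.approx(1.0 / 0.3)

    def test_no_cover_is_infinite_and_logged(self, site_pair, caplog):
        a, b = site_pair
        with caplog.at_level("WARNING"):
            val = lrt_pair(a, b, strip_map([1000], [0.0]), 2012)
        assert val == math.inf
        assert any("infinite" in r.message for r in caplog.records)

    def test_missing_era_is_validation_error(self, site_pair):
        a, b = site_pair
        with pytest.raises(ValidationError, match="era"):
            lrt_pair(a, b, strip_map([1000], [0.3]), 1860)

    def test_symmetry_and_scale_invariance(self):
        m = strip_map([300, 700], [0.15, 0.6])
        a = SiteSample("A", OX + 50, OY + 100, "P")
        b = SiteSample("B", OX + 950, OY + 900, "P")
        assert lrt_pair(a, b, m, 2012) == lrt_pair(b, a, m, 2012)
        # scale all geometry x3: Li/LT ratios unchanged
        m3 = CountyEraMap(
            counties={
                cid: box(*(3 * np.array(g.bounds))) for cid, g in m.counties.items()
            },
            proportions=m.proportions,
        )
        a3 = SiteSample("A", 3 * a.x, 3 * a.y, "P")
        b3 = SiteSample("B", 3 * b.x, 3 * b.y, "P")
        assert lrt_pair(a3, b3, m3, 2012) == pytest.approx(lrt_pair(a, b, m, 2012), rel=1e-12)

    def test_lrt_at_least_one_and_monotone_in_cover(self, site_pair):
        a, b = site_pair
        rng = np.random.default_rng(0)
        for _ in range(20):
            props = list(rng.uniform(0, 1, 4))
            m = strip_map([250] * 4, props)
            val = lrt_pair(a, b, m, 2012)
            assert val >= 1.0 - 1e-12
            # raising any single Z never increases LRT
            i = rng.integers(0, 4)
            raised = props.copy()
            raised[i] = min(1.0, raised[i] + 0.3)
            assert lrt_pair(a, b, strip_map([250] * 4, raised), 2012) <= val + 1e-12

    def test_shared_boundary_assigned_deterministically(self):
        # transect runs exactly along the boundary between Ca (above) and Cb
        m = CountyEraMap(
            counties={
                "Cb": box(OX, OY, OX + 1000, OY + 500),
                "Ca": box(OX, OY + 500, OX + 1000, OY + 1000),
            },
            proportions={2012: {"Ca": 0.5, "Cb": 0.25}},
        )
        a = SiteSample("A", OX, OY + 500.0, "P")
        b = SiteSample("B", OX + 1000, OY + 500.0, "P")
        segs = segment_path(a, b, m)
        # lexicographically smaller county_id wins the tie
        assert segs.segments == [("Ca", pytest.approx(1000.0))]
        assert lrt_pair(a, b, m, 2012) == pytest.approx(2.0)


class TestMatrices:
    def make_sites(self, n, rng):
        xy = rng.uniform(100, 900, size=(n, 2))
        return [
            SiteSample(f"S{i}", OX + x, OY + y, f"P{i}") for i, (x, y) in enumerate(xy)
        ]

    def test_uniform_cover_degenerate_standardization(self):
        m = strip_map([1000], [0.5])
        sites = [
            SiteSample("S1", OX + 100, OY + 100, "P1"),
            SiteSample("S2", OX + 500, OY + 500, "P2"),
            SiteSample("S3", OX + 900, OY + 200, "P3"),
        ]
        with pytest.raises(ValidationError, match="SD"):
            lrt_matrix(sites, m, 2012, standardize=True)
        out = lrt_matrix(sites, m, 2012, standardize=False)
        tri = out.upper_triangle()
        assert np.allclose(tri, 2.0)

    def test_standardized_upper_triangle_has_unit_sd(self):
        rng = np.random.default_rng(1)
        m = strip_map([200, 300, 250, 250], list(rng.uniform(0.05, 0.9, 4)))
        sites = self.make_sites(5, rng)
        out = lrt_matrix(sites, m, 2012, standardize=True)
        assert np.std(out.upper_triangle(), ddof=1) == pytest.approx(1.0)

    def test_lrt_matrix_matches_point_classification_oracle(self):
        rng = np.random.default_rng(2)
        m = strip_map([250, 250, 250, 250], list(rng.uniform(0.05, 0.9, 4)))
        sites = self.make_sites(4, rng)
        out = lrt_matrix(sites, m, 2012, standardize=False)
        for i in range(4):
            for j in range(i + 1, 4):
                oracle = mc_lrt(sites[i], sites[j], m, 2012)
                assert out.values[i, j] == pytest.approx(oracle, rel=0.005)

    def test_distance_matrix_345(self):
        sites = [SiteSample("A", OX, OY, "P"), SiteSample("B", OX + 3, OY + 4, "P")]
        out = geographic_distance_matrix(sites, standardize=False)
        assert out.values[0, 1] == pytest.approx(5.0)

    def test_distance_matrix_permutation_invariance_and_oracle(self):
        rng = np.random.default_rng(3)
        sites = self.make_sites(5, rng)
        out = geographic_distance_matrix(sites, standardize=False)
        # brute-force double loop
        for i in range(5):
            for j in range(5):
                d = math.hypot(sites[i].x - sites[j].x, sites[i].y - sites[j].y)
                assert out.values[i, j] == pytest.approx(d)
        perm = [3, 1, 4, 0, 2]
        out_p = geographic_distance_matrix([sites[i] for i in perm], standardize=False)
        assert np.allclose(
            out_p.values, out.values[np.ix_(perm, perm)]
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "fst")


class TestLrtProperties:
    """Model-level invariants of the resistance metric, property-tested."""

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        props=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        frac=st.floats(0.05, 0.95),
    )
    def test_bounds_symmetry_and_cover_monotonicity(self, props, frac):
        widths = [1000.0 / len(props)] * len(props)
        m = strip_map(widths, props)
        a = SiteSample("A", OX + 1000.0 * 0.01, OY + 500.0, "P")
        b = SiteSample("B", OX + 1000.0 * max(frac, 0.02), OY + 500.0, "P")
        val = lrt_pair(a, b, m, 2012)
        assert val >= 1.0 - 1e-12
        assert lrt_pair(b, a, m, 2012) == val
        richer = strip_map(widths, [min(1.0, p * 1.5) for p in props])
        assert lrt_pair(a, b, richer, 2012) <= val + 1e-12
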