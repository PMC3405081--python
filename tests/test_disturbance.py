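import numpy as np
import pytest
from shapely.geometry import LineString, Point

from windsift.disturbance import (
    ConfigurationError,
    impervious_mask,
    landcover_mask,
    linear_mask,
    point_buffer_mask,
    topo_change_mask,
    union_masks,
    well_density,
    well_field_mask,
)
from windsift.features import FeatureSet
from windsift.grid import AlignmentError, Mask

from conftest import make_template, mask_from_array


def points(coords):
    return FeatureSet(kind="point", geometries=[Point(x, y) for x, y in coords])


class TestLandcoverMask:
    def test_uniform_disturbed_code(self):
        g = make_template(3, 3).like(np.full((3, 3), 82), nodata=255)
        assert landcover_mask(g, {82}).values.all()

    def test_empty_code_set_all_zeros(self):
        g = make_template(3, 3).like(np.full((3, 3), 82), nodata=255)
        assert not landcover_mask(g, set()).values.any()

    def test_indicator_cell_by_cell(self):
        codes = np.array([[82, 71, 11], [71, 82, 82], [11, 11, 71]])
        g = make_template(3, 3).like(codes, nodata=255)
        m = landcover_mask(g, {82})
        for r in range(3):
            for c in range(3):
                assert m.values[r, c] == (codes[r, c] == 82)

    def test_unknown_code_raises(self):
        g = make_template(3, 3).like(np.full((3, 3), 82), nodata=255)
        with pytest.raises(ConfigurationError, match="schema"):
            landcover_mask(g, {82, 999}, schema_codes={82, 71})

    def test_nodata_propagates(self):
        codes = np.array([[82, 255], [71, 82]])
        g = make_template(2, 2).like(codes, nodata=255)
        m = landcover_mask(g, {82})
        assert m.grid.data[0, 1] == 255


class TestTopoChangeMask:
    def test_all_zero_change_is_clean(self, template):
        topo = template.like(np.zeros(template.shape))
        lc = template.like(np.full(template.shape, 71))
        m = topo_change_mask(topo, lc, {71: 10.21})
        assert not m.values.any()

    def test_single_cell_over_threshold(self, template):
        change = np.zeros(template.shape)
        change[2, 3] = 12.0
        topo = template.like(change)
        lc = template.like(np.full(template.shape, 71))
        m = topo_change_mask(topo, lc, {71: 10.21})
        assert m.values[2, 3] and m.cell_count == 1

    def test_per_code_thresholds_match_bruteforce(self, rng):
        t = make_template(16, 16)
        lc_codes = rng.choice([71, 82, 41], size=t.shape)
        change = rng.uniform(0, 25, size=t.shape)
        thresholds = {71: 10.21, 82: 14.0, 41: 17.57}
        m = topo_change_mask(t.like(change), t.like(lc_codes), thresholds)
        for r in range(16):
            for c in range(16):
                expected = abs(change[r, c]) >= thresholds[int(lc_codes[r, c])]
                assert m.values[r, c] == expected

    def test_missing_threshold_raises(self, template):
        topo = template.like(np.zeros(template.shape))
        lc = template.like(np.full(template.shape, 41))
        with pytest.raises(ConfigurationError, match="41"):
            topo_change_mask(topo, lc, {71: 10.21})


def brute_force_density(wells, grid, bandwidth):
    """O(cells x wells) quartic kernel sum, wells per km^2."""
    X, Y = grid.cell_centers()
    out = np.zeros(grid.shape)
    for x, y in wells.coords():
        d2 = (X - x) ** 2 + (Y - y) ** 2
        u2 = d2 / bandwidth**2
        out += np.where(u2 < 1, 3.0 / (np.pi * bandwidth**2) * (1 - u2) ** 2, 0.0)
    return out * 1e6


class TestWellFieldMask:
    def test_zero_wells_all_zero(self, template):
        m = well_field_mask(points([]), template, 1000.0, 1.0)
        assert not m.values.any()

    def test_single_well_support_disk(self):
        t = make_template(64, 64, cell=100.0)
        w = points([(3200.0, 3200.0)])
        bandwidth = 1000.0
        m = well_field_mask(w, t, bandwidth, threshold=1e-9)
        X, Y = t.cell_centers()
        d = np.hypot(X - 3200.0, Y - 3200.0)
        inside = d < bandwidth - t.cell_size  # one-cell tolerance
        outside = d > bandwidth + t.cell_size
        assert m.values[inside].all()
        assert not m.values[outside].any()

    def test_matches_direct_summation_oracle(self, rng):
        t = make_template(64, 64, cell=100.0)
        w, s, e, n = t.bounds
        coords = np.column_stack(
            [rng.uniform(w, e, size=10), rng.uniform(s, n, size=10)]
        )
        wells = points(coords)
        bandwidth, threshold = 900.0, 2.0
        density = well_density(wells, t, bandwidth)
        oracle = brute_force_density(wells, t, bandwidth)
        np.testing.assert_allclose(density, oracle, rtol=1e-10, atol=1e-12)
        m = well_field_mask(wells, t, bandwidth, threshold)
        assert np.array_equal(m.values, oracle >= threshold)

    def test_density_integrates_to_well_count(self):
        t = make_template(64, 64, cell=100.0)
        wells = points([(3200.0, 3200.0), (2000.0, 4000.0)])
        density = well_density(wells, t, 800.0)
        total = density.sum() * t.cell_area_km2
        assert total == pytest.approx(len(wells), rel=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        t = make_template(32, 32, cell=100.0)
        coords = rng.uniform(0, 3200, size=(15, 2))
        lo = well_field_mask(points(coords), t, 800.0, 1.0)
        hi = well_field_mask(points(coords), t, 800.0, 3.0)
        assert (~hi.values | lo.values).all()  # hi subset of lo


class TestLinearMask:
    def test_empty_lines_all_zero(self, template):
        m = linear_mask(FeatureSet(kind="line"), template, 30.0)
        assert not m.values.any()

    def test_horizontal_line_hits_full_row(self):
        t = make_template(8, 8, cell=100.0)
        y = 800.0 - 2 * 100.0 - 50.0  # center height of row 2
        line = FeatureSet(kind="line", geometries=[LineString([(0, y), (799, y)])])
        m = linear_mask(line, t, 30.0)
        assert m.values[2, :].all()
        assert m.cell_count == 8

    def test_random_polyline_matches_sampling_oracle(self, rng):
        t = make_template(32, 32, cell=100.0)
        vertices = rng.uniform(50, 3150, size=(6, 2))
        line = FeatureSet(kind="line", geometries=[LineString(vertices)])
        resolution = 100.0  # sub-cell == analysis cell for exact comparison
        m = linear_mask(line, t, resolution)
        # oracle: dense point sampling along the line (0.5 m step, so even
        # short corner clips of a cell footprint receive a sample)
        import shapely

        geom = line.geometries[0]
        distances = np.arange(0.0, geom.length, 0.5)
        pts = shapely.line_interpolate_point(geom, distances)
        xs = shapely.get_x(pts)
        ys = shapely.get_y(pts)
        rr, cc = t.xy_to_rowcol(xs, ys)
        expected = np.zeros(t.shape, dtype=bool)
        expected[rr, cc] = True
        assert np.array_equal(m.values, expected)


class TestPointBufferMask:
    def test_radius_zero_marks_containing_cells_only(self):
        t = make_template(8, 8, cell=100.0)
        m = point_buffer_mask(points([(130.0, 760.0)]), t, 0.0)
        assert m.cell_count == 1
        assert m.values[0, 1]

    def test_buffer_equals_per_cell_euclidean_check(self):
        t = make_template(10, 10, cell=100.0)
        pt = (430.0, 520.0)
        m = point_buffer_mask(points([pt]), t, 300.0)
        X, Y = t.cell_centers()
        expected = np.hypot(X - pt[0], Y - pt[1]) <= 300.0
        expected[4, 4] = True  # containing cell always marked
        assert np.array_equal(m.values, expected)

    def test_union_of_singletons(self):
        t = make_template(10, 10, cell=100.0)
        pts = [(200.0, 300.0), (400.0, 350.0)]
        both = point_buffer_mask(points(pts), t, 250.0)
        singles = [point_buffer_mask(points([p]), t, 250.0) for p in pts]
        assert np.array_equal(both.values, singles[0].values | singles[1].values)


class TestUnionMasks:
    def test_identity_with_zeros(self, rng):
        a = mask_from_array(rng.random((8, 8)) < 0.4)
        zero = mask_from_array(np.zeros((8, 8)))
        assert np.array_equal(union_masks([a, zero]).values, a.values)

    def test_commutative_and_idempotent(self, rng):
        a = mask_from_array(rng.random((8, 8)) < 0.4)
        b = mask_from_array(rng.random((8, 8)) < 0.4)
        ab = union_masks([a, b]).values
        ba = union_masks([b, a]).values
        aa = union_masks([a, a]).values
        assert np.array_equal(ab, ba)
        assert np.array_equal(aa, a.values)

    def test_disjoint_cardinality_adds(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[:2] = True
        b[4:] = True
        u = union_masks([mask_from_array(a), mask_from_array(b)])
        assert u.cell_count == a.sum() + b.sum()

    def test_misaligned_raises(self):
        a = mask_from_array(np.zeros((6, 6)))
        b = mask_from_array(np.zeros((5, 6)))
        with pytest.raises(AlignmentError):
            union_masks([a, b])

    def test_provenance_concatenates(self):
        a = mask_from_array(np.zeros((4, 4)))
        a.provenance = ["landcover"]
        b = mask_from_array(np.zeros((4, 4)))
        b.provenance = ["wells"]
        assert union_masks([a, b]).provenance == ["landcover", "wells"]


class TestImpervious:
    def test_strict_threshold(self, template):
        frac = np.zeros(template.shape)
        frac[0, 0] = 0.5
        frac[0, 1] = 0.0
        m = impervious_mask(template.like(frac), threshold=0.0)
        assert m.values[0, 0] and not m.values[0, 1]
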