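import numpy as np
import pytest
import yaml
from shapely import box as shapely_box
from shapely.geometry import LineString, Point

from windsift import io as wio
from windsift.disturbance import union_masks
from windsift.exclusions import (
    DataError,
    ExclusionRule,
    RuleError,
    RuleSet,
    compile_rule,
    compose_exclusions,
    repeated_stopover_sites,
)
from windsift.features import FeatureSet
from windsift.synth import LandscapeParams, generate_landscape

from conftest import make_template


def obs(records):
    return FeatureSet(
        kind="point",
        geometries=[Point(x, y) for x, y, _ in records],
        attributes=[{"date": d} for _, _, d in records],
    )


class TestRepeatedStopoverRule:
    def test_multiple_years_qualifies(self):
        sites = repeated_stopover_sites(
            obs([(10, 10, "2010-05-01"), (12, 11, "2012-04-30")]), site_radius=50
        )
        assert len(sites) == 1
        assert sites.attributes[0]["n_years"] == 2

    def test_three_days_one_year_qualifies(self):
        sites = repeated_stopover_sites(
            obs(
                [
                    (10, 10, "2011-04-01"),
                    (11, 10, "2011-04-02"),
                    (10, 11, "2011-04-03"),
                ]
            ),
            site_radius=50,
        )
        assert len(sites) == 1
        assert sites.attributes[0]["max_days_one_year"] == 3

    def test_two_days_one_year_does_not_qualify(self):
        sites = repeated_stopover_sites(
            obs([(10, 10, "2011-04-01"), (11, 10, "2011-04-02")]), site_radius=50
        )
        assert len(sites) == 0

    def test_repeat_sightings_same_day_do_not_qualify(self):
        sites = repeated_stopover_sites(
            obs([(10, 10, "2011-04-01")] * 4), site_radius=50
        )
        assert len(sites) == 0

    def test_distant_observations_form_separate_sites(self):
        # two far-apart locations, each spanning two years
        records = [
            (0, 0, "2010-05-01"),
            (0, 0, "2011-05-01"),
            (5000, 5000, "2010-05-02"),
            (5000, 5000, "2012-05-02"),
        ]
        sites = repeated_stopover_sites(obs(records), site_radius=100)
        assert len(sites) == 2

    def test_undated_observation_names_record(self):
        bad = FeatureSet(
            kind="point",
            geometries=[Point(0, 0), Point(1, 1)],
            attributes=[{"date": "2010-05-01"}, {"date": None}],
        )
        with pytest.raises(DataError, match="observation 1"):
            repeated_stopover_sites(bad)


class TestCompileRule:
    def test_density_threshold_inclusive(self, template):
        grid = template.like(np.full(template.shape, 104.0))
        rule = ExclusionRule("wf", "waterfowl_density", "density_at_least",
                             {"threshold": 104.0})
        m = compile_rule(rule, {"waterfowl_density": grid}, template)
        assert m.values.all()

    def test_category_in_set_enumeration(self, rng, template):
        cats = rng.integers(1, 7, size=template.shape)
        rule = ExclusionRule("ne", "sensitivity", "category_in_set",
                             {"categories": [3, 4, 5, 6]})
        m = compile_rule(rule, {"sensitivity": template.like(cats)}, template)
        assert np.array_equal(m.values, np.isin(cats, [3, 4, 5, 6]))

    def test_category_at_least(self, rng, template):
        cats = rng.integers(1, 5, size=template.shape)
        rule = ExclusionRule("mt", "caps", "category_at_least", {"min_category": 3})
        m = compile_rule(rule, {"caps": template.like(cats)}, template)
        assert np.array_equal(m.values, cats >= 3)

    def test_polygon_burn_empty_layer(self, template):
        rule = ExclusionRule("pa", "polys", "polygon_burn", {})
        m = compile_rule(rule, {"polys": FeatureSet(kind="polygon")}, template)
        assert not m.values.any()

    def test_polygon_burn_cell_centers(self, template):
        poly = FeatureSet(kind="polygon", geometries=[shapely_box(0, 500, 300, 800)])
        rule = ExclusionRule("pa", "polys", "polygon_burn", {})
        m = compile_rule(rule, {"polys": poly}, template)
        X, Y = template.cell_centers()
        expected = (X < 300) & (Y > 500)
        assert np.array_equal(m.values, expected)

    def test_polygon_burn_attribute_filter(self, template):
        polys = FeatureSet(
            kind="polygon",
            geometries=[shapely_box(0, 0, 800, 800), shapely_box(0, 0, 100, 100)],
            attributes=[{"gap_code": 3}, {"gap_code": 1}],
        )
        rule = ExclusionRule(
            "gap", "protected_areas", "polygon_burn",
            {"where": {"field": "gap_code", "in": [1, 2]}},
        )
        m = compile_rule(rule, {"protected_areas": polys}, template)
        assert m.cell_count == 1  # only the small GAP-1 box burns

    def test_missing_layer_raises(self, template):
        rule = ExclusionRule("x", "absent", "polygon_burn", {})
        with pytest.raises(RuleError, match="absent"):
            compile_rule(rule, {}, template)

    def test_type_mismatch_raises(self, template):
        rule = ExclusionRule("x", "wells", "polygon_burn", {})
        layer = FeatureSet(kind="point", geometries=[Point(1, 1)])
        with pytest.raises(RuleError, match="polygon"):
            compile_rule(rule, {"wells": layer}, template)

    def test_unknown_operator_rejected_at_construction(self):
        with pytest.raises(RuleError, match="operator"):
            ExclusionRule("x", "layer", "frobnicate", {})

    @pytest.mark.parametrize("radius_small,radius_big", [(200.0, 500.0)])
    def test_buffer_monotonicity(self, template, radius_small, radius_big):
        layer = FeatureSet(kind="line", geometries=[LineString([(0, 400), (800, 400)])])
        small = compile_rule(
            ExclusionRule("r1", "rivers", "line_buffer", {"radius": radius_small}),
            {"rivers": layer}, template,
        )
        big = compile_rule(
            ExclusionRule("r2", "rivers", "line_buffer", {"radius": radius_big}),
            {"rivers": layer}, template,
        )
        assert (~small.values | big.values).all()


class TestComposeExclusions:
    def fixture_layers(self, seed=3):
        L = generate_landscape(
            LandscapeParams(grid_shape=(64, 64), seed=seed, n_wells=40)
        )
        return L.layer_map(), L.landcover

    def test_empty_ruleset_all_zero(self, template):
        m = compose_exclusions(RuleSet("nowhere", []), {}, template)
        assert not m.values.any()

    def test_singleton_equals_compile_rule(self):
        layers, template = self.fixture_layers()
        rule = ExclusionRule("wf", "waterfowl_density", "density_at_least",
                             {"threshold": 80.0})
        single = compile_rule(rule, layers, template)
        composed = compose_exclusions(RuleSet("one", [rule]), layers, template)
        assert np.array_equal(single.values, composed.values)

    def test_dakotas_ruleset_equals_union_of_singletons(self):
        layers, template = self.fixture_layers()
        ruleset = wio.load_shipped_ruleset("north_south_dakota")
        composed = compose_exclusions(ruleset, layers, template)
        singles = [compile_rule(r, layers, template) for r in ruleset.rules]
        assert np.array_equal(composed.values, union_masks(singles).values)
        assert set(composed.provenance) == {r.rule_id for r in ruleset.rules}

    def test_order_independence(self):
        layers, template = self.fixture_layers()
        ruleset = wio.load_shipped_ruleset("north_south_dakota")
        reordered = RuleSet(ruleset.jurisdiction, list(reversed(ruleset.rules)))
        a = compose_exclusions(ruleset, layers, template)
        b = compose_exclusions(reordered, layers, template)
        assert np.array_equal(a.values, b.values)

    def test_failing_rule_names_rule_id(self):
        layers, template = self.fixture_layers()
        bad = RuleSet(
            "broken",
            [ExclusionRule("bad_rule", "no_such_layer", "polygon_burn", {})],
        )
        with pytest.raises(RuleError, match="bad_rule"):
            compose_exclusions(bad, layers, template)

    def test_duplicate_rule_ids_rejected(self):
        r = ExclusionRule("dup", "priority_polygons", "polygon_burn", {})
        with pytest.raises(RuleError, match="dup"):
            RuleSet("x", [r, r])


class TestShippedRuleSets:
    def test_five_rulesets_ship(self):
        names = wio.shipped_ruleset_names()
        assert names == [
            "alberta_saskatchewan",
            "montana",
            "nebraska",
            "north_south_dakota",
            "wyoming",
        ]

    @pytest.mark.parametrize("name", [
        "alberta_saskatchewan", "montana", "nebraska",
        "north_south_dakota", "wyoming",
    ])
    def test_roundtrip_lossless(self, name, tmp_path):
        ruleset = wio.load_shipped_ruleset(name)
        path = tmp_path / f"{name}.yaml"
        wio.write_ruleset(ruleset, path)
        again = wio.read_ruleset(path)
        assert again.to_dict() == ruleset.to_dict()

    @pytest.mark.parametrize("name", [
        "alberta_saskatchewan", "montana", "nebraska",
        "north_south_dakota", "wyoming",
    ])
    def test_all_rulesets_compile_on_synthetic_layers(self, name):
        L = generate_landscape(LandscapeParams(grid_shape=(48, 48), seed=11))
        m = compose_exclusions(
            wio.load_shipped_ruleset(name), L.layer_map(), L.landcover
        )
        assert m.grid.shape == (48, 48)
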