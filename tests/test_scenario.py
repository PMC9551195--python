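"""Scenario engine: ratio combination, cover prediction, summaries."""

import numpy as np
import pytest

from cumimpact import (GridSpec, HabitatLayer, PressureLayer, Scenario,
                       apply_scenario, combined_rr, compare_scenarios,
                       percent_total_change, summarize_scenario)
from cumimpact.scenario import CoverageGapError, round_half_away
from cumimpact.seascape import AlignmentError
from tests.conftest import make_score


def matrix_of(*scores):
    return {(s.habitat_id, s.pressure_set): s for s in scores}


def binary_layer(grid, pressure_id, mask=None):
    arr = np.ones(grid.shape) if mask is None else mask.astype(float)
    return PressureLayer(pressure_id, grid, arr)


class TestCombinedRR:
    def test_no_active_pressure_is_neutral(self):
        assert combined_rr({}, "reef", {}) == (1.0, 1.0, 1.0)
        assert combined_rr({}, "reef", {"round_goby": 0.0}) == (1.0, 1.0, 1.0)

    def test_single_binary_pass_through(self):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384))
        lo, me, hi = combined_rr(m, "reef", {"round_goby": 1.0})
        assert me == pytest.approx(0.384)

    def test_product_rule_for_independent_binaries(self):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.8),
                      make_score("reef", {"mud_crab"}, 0.5))
        _, me, _ = combined_rr(m, "reef", {"round_goby": 1, "mud_crab": 1})
        assert me == pytest.approx(0.40)

    def test_direct_joint_score_overrides_product(self):
        """Jointly observed evidence can show a weaker combined effect than
        either invader alone; the direct score must win over composition."""
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384),
                      make_score("reef", {"mud_crab"}, 0.7),
                      make_score("reef", {"round_goby", "mud_crab"}, 0.5))
        _, me, _ = combined_rr(m, "reef", {"round_goby": 1, "mud_crab": 1})
        assert me == pytest.approx(0.5)
        assert me > 0.384 * 0.7  # distinguishable from the product rule

    def test_nutrient_intensity_exponent(self):
        m = matrix_of(make_score("reef", {"nutrient_load"}, 0.8))
        _, me, _ = combined_rr(m, "reef", {"nutrient_load": 1.0},
                               nutrient_multiplier=0.75)
        assert me == pytest.approx(0.8 ** 0.75)
        assert me == pytest.approx(0.8459, abs=2e-4)

    def test_windpark_footprint_exponent(self):
        m = matrix_of(make_score("sandbank", {"wind_park"}, 2.0,
                                 rr_low=1.5, rr_high=3.0))
        lo, me, hi = combined_rr(m, "sandbank", {"wind_park": 0.0123})
        assert me == pytest.approx(2.0 ** 0.0123)
        assert lo <= me <= hi

    def test_coverage_gap_names_habitat_and_pressure(self):
        with pytest.raises(CoverageGapError) as exc:
            combined_rr({}, "zostera", {"round_goby": 1.0})
        assert exc.value.habitat_id == "zostera"
        assert exc.value.pressure == "round_goby"

    def test_bounds_bracket_mean(self):
        m = matrix_of(
            make_score("reef", {"round_goby"}, 0.4, rr_low=0.2, rr_high=0.9),
            make_score("reef", {"nutrient_load"}, 0.9, rr_low=0.5,
                       rr_high=1.4))
        lo, me, hi = combined_rr(m, "reef", {"round_goby": 1,
                                             "nutrient_load": 1.2})
        assert lo <= me <= hi


class TestApplyScenario:
    def test_identity_scenario_preserves_cover(self, uniform_reef):
        scenario = Scenario("identity", {})
        result = apply_scenario(uniform_reef, scenario, {})
        np.testing.assert_array_equal(result.cover_mean, uniform_reef.cover)
        np.testing.assert_array_equal(result.cover_min, uniform_reef.cover)
        assert result.summary["total_pct_change"] == 0
        assert result.summary["n_impacted_cells"] == 0

    def test_single_cell_multiplication(self, small_grid):
        cover = np.zeros(small_grid.shape)
        cover[4, 4] = 0.5
        habitat = HabitatLayer("reef", small_grid, cover)
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384))
        scenario = Scenario("s3", {"round_goby":
                                   binary_layer(small_grid, "round_goby")})
        result = apply_scenario(habitat, scenario, m)
        assert result.cover_mean[4, 4] == pytest.approx(0.5 * 0.384)
        assert result.pct_change_mean[4, 4] == pytest.approx(-61.6)
        assert result.summary["n_impacted_cells"] == 1

    def test_full_cover_cannot_gain(self, small_grid):
        habitat = HabitatLayer("sandbank", small_grid,
                               np.ones(small_grid.shape))
        m = matrix_of(make_score("sandbank", {"wind_park"}, 2.0,
                                 rr_low=1.5, rr_high=3.0))
        wind = PressureLayer("wind_park", small_grid,
                             np.full(small_grid.shape, 1.0))
        result = apply_scenario(habitat, Scenario("s4", {"wind_park": wind}), m)
        assert result.cover_mean.max() == 1.0
        np.testing.assert_array_equal(result.cover_mean, habitat.cover)

    def test_windpark_creation_bounded_by_footprint(self, small_grid):
        cover = np.full(small_grid.shape, 0.3)
        cover[0, 0] = 0.0  # bare soft bottom inside the park
        habitat = HabitatLayer("suspension_feeders", small_grid, cover)
        f = 0.0123
        wind = PressureLayer("wind_park", small_grid,
                             np.full(small_grid.shape, f))
        m = matrix_of(make_score("suspension_feeders", {"wind_park"}, 3.0,
                                 rr_low=1.5, rr_high=5.0))
        result = apply_scenario(habitat,
                                Scenario("s4", {"wind_park": wind}), m)
        assert 0 < result.cover_mean[0, 0] <= f
        assert result.cover_min[0, 0] <= result.cover_mean[0, 0]
        assert result.cover_mean[0, 0] <= result.cover_max[0, 0]

    def test_no_creation_without_positive_response(self, small_grid):
        cover = np.zeros(small_grid.shape)
        cover[1, 1] = 0.4
        habitat = HabitatLayer("fucus", small_grid, cover)
        wind = PressureLayer("wind_park", small_grid,
                             np.full(small_grid.shape, 0.0123))
        m = matrix_of(make_score("fucus", {"wind_park"}, 0.7))
        result = apply_scenario(habitat, Scenario("s4", {"wind_park": wind}), m)
        assert result.cover_mean[0, 0] == 0.0  # rr < 1 creates nothing

    def test_locality(self, small_grid):
        """Perturbing the pressure in one cell changes no other cell."""
        rng = np.random.default_rng(3)
        cover = rng.uniform(0.1, 0.9, small_grid.shape)
        habitat = HabitatLayer("reef", small_grid, cover)
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384))
        mask = rng.random(small_grid.shape) < 0.5
        base = apply_scenario(
            habitat, Scenario("a", {"round_goby":
                                    binary_layer(small_grid, "round_goby",
                                                 mask)}), m)
        flipped = mask.copy()
        flipped[2, 2] = ~flipped[2, 2]
        pert = apply_scenario(
            habitat, Scenario("b", {"round_goby":
                                    binary_layer(small_grid, "round_goby",
                                                 flipped)}), m)
        delta = pert.cover_mean != base.cover_mean
        assert delta[2, 2]
        delta[2, 2] = False
        assert not delta.any()

    def test_alignment_failure(self, uniform_reef):
        other = GridSpec(n_rows=8, n_cols=10, origin_x=0.0, origin_y=0.0)
        goby = binary_layer(other, "round_goby")
        m = matrix_of(make_score("reef", {"round_goby"}, 0.5))
        with pytest.raises(AlignmentError):
            apply_scenario(uniform_reef, Scenario("s", {"round_goby": goby}), m)

    def test_regional_additivity(self, uniform_reef, small_grid):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.6))
        result = apply_scenario(
            uniform_reef,
            Scenario("s", {"round_goby": binary_layer(small_grid,
                                                      "round_goby")}), m)
        per_cell = (result.cover_mean - uniform_reef.cover).sum()
        assert result.summary["areal_change_km2"] == pytest.approx(per_cell)


class TestSummary:
    @pytest.mark.parametrize("areal,total,expected", [
        (-506, 3180, -16),
        (1024, 7780, 13),
        (0, 100, 0),
    ])
    def test_total_percent_bookkeeping(self, areal, total, expected):
        assert percent_total_change(areal, total) == expected

    def test_zero_cover_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_total_change(-10, 0)

    @pytest.mark.parametrize("x,expected", [
        (15.5, 16), (-15.5, -16), (0.4, 0), (-0.4, 0), (13.16, 13),
        (-30.6, -31),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_summary_fields_consistent(self, uniform_reef, small_grid):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384))
        result = apply_scenario(
            uniform_reef,
            Scenario("s", {"round_goby": binary_layer(small_grid,
                                                      "round_goby")}), m)
        s = result.summary
        assert s["n_habitat_cells"] == small_grid.n_rows * small_grid.n_cols
        assert s["total_cover_km2"] == pytest.approx(0.5 * s["n_habitat_cells"])
        assert s["total_pct_change"] == round_half_away(
            100 * s["areal_change_km2"] / s["total_cover_km2"])

    def test_recomputed_summary_matches(self, uniform_reef, small_grid):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.384))
        result = apply_scenario(
            uniform_reef,
            Scenario("s", {"round_goby": binary_layer(small_grid,
                                                      "round_goby")}), m)
        redo = summarize_scenario(result)
        assert redo["total_pct_change"] == result.summary["total_pct_change"]
        assert redo["areal_change_km2"] == pytest.approx(
            result.summary["areal_change_km2"])


class TestCompare:
    def _result(self, habitat, scenario, m):
        return apply_scenario(habitat, scenario, m)

    def test_self_comparison_zero(self, uniform_reef, small_grid):
        m = matrix_of(make_score("reef", {"round_goby"}, 0.5))
        sc = Scenario("a", {"round_goby": binary_layer(small_grid,
                                                       "round_goby")})
        r = self._result(uniform_reef, sc, m)
        diff, delta = compare_scenarios(r, r)
        assert not diff.any()
        assert delta["delta_total_pct_change"] == 0

    def test_single_cell_difference_in_points(self, small_grid):
        cover = np.zeros(small_grid.shape)
        cover[0, 0] = 1.0
        habitat = HabitatLayer("reef", small_grid, cover)
        m_a = matrix_of(make_score("reef", {"round_goby"}, 0.3))
        m_b = matrix_of(make_score("reef", {"round_goby"}, 0.4))
        goby = binary_layer(small_grid, "round_goby")
        a = apply_scenario(habitat, Scenario("a", {"round_goby": goby}), m_a)
        b = apply_scenario(habitat, Scenario("b", {"round_goby": goby}), m_b)
        diff, _ = compare_scenarios(a, b)
        assert diff[0, 0] == pytest.approx(10.0)  # 0.3 -> 0.4 cover = +10 pp

    def test_nutrient_reduction_dominates(self, small_grid):
        """A 25 % load cut can only help habitats harmed by nutrients."""
        rng = np.random.default_rng(8)
        habitat = HabitatLayer("zostera", small_grid,
                               rng.uniform(0, 1, small_grid.shape))
        m = matrix_of(make_score("zostera", {"nutrient_load"}, 0.4))
        nutrient = PressureLayer("nutrient_load", small_grid,
                                 rng.uniform(0.2, 2.0, small_grid.shape))
        bau = apply_scenario(habitat, Scenario(
            "bau", {"nutrient_load": nutrient}, nutrient_multiplier=1.0), m)
        mai = apply_scenario(habitat, Scenario(
            "mai", {"nutrient_load": nutrient}, nutrient_multiplier=0.75), m)
        assert (mai.cover_mean >= bau.cover_mean - 1e-12).all()
        diff, delta = compare_scenarios(bau, mai)
        assert (diff >= -1e-9).all()
        assert delta["delta_total_pct_change"] >= 0

    def test_habitat_mismatch_rejected(self, uniform_reef, small_grid):
        other = HabitatLayer("sandbank", small_grid,
                             np.full(small_grid.shape, 0.5))
        m = matrix_of(make_score("reef", {"round_goby"}, 0.5),
                      make_score("sandbank", {"round_goby"}, 0.5))
        goby = binary_layer(small_grid, "round_goby")
        a = apply_scenario(uniform_reef, Scenario("a", {"round_goby": goby}), m)
        b = apply_scenario(other, Scenario("b", {"round_goby": goby}), m)
        with pytest.raises(ValueError, match="habitat mismatch"):
            compare_scenarios(a, b)
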