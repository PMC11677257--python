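"""Synthetic survey generator: determinism, trend recovery, conservation."""

import numpy as np
import pandas as pd
import pytest

from dietfootprint import (
    ConfigurationError,
    MappingError,
    RegimeSwitch,
    TrendSpec,
    ValidationError,
    aggregate_to_consumption,
    generate_survey,
    kg_year_to_g_day,
)

YEARS = range(2006, 2016)
IDENTITY = {f"IT_{g}": g for g in ("red_meat", "grains", "fish")}


def level_g_day(consumption: pd.DataFrame, group: str) -> pd.Series:
    block = consumption[consumption["item"] == group].set_index("year")
    return block["quantity"].map(kg_year_to_g_day)


class TestTrendSpec:
    def test_expected_levels_follow_segment_apcs(self):
        spec = TrendSpec(
            "fish", base_level=100.0, segment_apcs=(5.0, -2.0), change_points=(2010,)
        )
        levels = spec.expected_levels(YEARS)
        assert levels[0] == 100.0
        assert levels[4] == pytest.approx(100.0 * 1.05**4)
        assert levels[6] == pytest.approx(100.0 * 1.05**4 * 0.98**2)

    def test_segment_count_must_match_change_points(self):
        with pytest.raises(ValidationError, match="segment APCs"):
            TrendSpec("fish", 100.0, segment_apcs=(1.0,), change_points=(2010,))

    def test_change_point_outside_year_range_rejected(self):
        spec = TrendSpec("fish", 100.0, segment_apcs=(1.0, 2.0), change_points=(2020,))
        with pytest.raises(ValidationError, match="outside"):
            spec.expected_levels(YEARS)


class TestGenerateSurvey:
    def test_flat_noiseless_trend_is_exact(self):
        spec = TrendSpec("red_meat", base_level=100.0)
        survey = generate_survey([spec], 10, YEARS, seed=0)
        cons = aggregate_to_consumption(survey, IDENTITY)
        assert np.allclose(level_g_day(cons, "red_meat"), 100.0)

    def test_noiseless_apc_compounds_exactly(self):
        spec = TrendSpec("red_meat", base_level=100.0, segment_apcs=(5.0,))
        cons = aggregate_to_consumption(generate_survey([spec], 7, YEARS, seed=0), IDENTITY)
        got = level_g_day(cons, "red_meat").to_numpy()
        assert np.allclose(got, 100.0 * 1.05 ** np.arange(len(YEARS)))

    def test_seed_determinism(self):
        spec = TrendSpec("fish", 50.0, noise_cv=0.3)
        a = generate_survey([spec], 50, YEARS, seed=7).records
        b = generate_survey([spec], 50, YEARS, seed=7).records
        pd.testing.assert_frame_equal(a, b)
        c = generate_survey([spec], 50, YEARS, seed=8).records
        assert not a["quantity_kg_fortnight"].equals(c["quantity_kg_fortnight"])

    def test_overlapping_specs_rejected(self):
        with pytest.raises(ConfigurationError, match="overlapping"):
            generate_survey(
                [TrendSpec("fish", 1.0), TrendSpec("fish", 2.0)], 5, YEARS, seed=0
            )

    def test_lognormal_noise_recovers_generating_slope(self):
        """Fitted log-linear slope is within 3 SE of ln(0.98) at APC −2%."""
        spec = TrendSpec("fish", base_level=100.0, segment_apcs=(-2.0,), noise_cv=0.2)
        survey = generate_survey([spec], 1000, YEARS, seed=123)
        cons = aggregate_to_consumption(survey, IDENTITY)
        y = np.log(level_g_day(cons, "fish").to_numpy())
        t = np.arange(len(YEARS), dtype=float)
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(
            resid @ resid / (len(t) - 2) / np.sum((t - t.mean()) ** 2)
        )
        assert abs(beta[1] - np.log(0.98)) < 3 * se

    def test_mean_recovery_at_1000_households(self):
        """Yearly aggregates converge on the spec trajectory (3 SE)."""
        spec = TrendSpec("grains", base_level=80.0, noise_cv=0.2)
        survey = generate_survey([spec], 1000, YEARS, seed=42)
        cons = aggregate_to_consumption(survey, IDENTITY)
        got = level_g_day(cons, "grains").to_numpy()
        se = 80.0 * 0.2 / np.sqrt(1000)
        assert np.all(np.abs(got - 80.0) < 3 * se)


class TestAggregation:
    def test_single_household_fortnight_scaling(self):
        records = pd.DataFrame(
            {"year": [2006], "household_id": [0], "item_code": ["IT_fish"],
             "quantity_kg_fortnight": [1.4], "household_size": [1.0]}
        )
        out = aggregate_to_consumption(records, IDENTITY)
        assert out["quantity"].iloc[0] == pytest.approx(36.5)  # 1.4 x 365/14
        assert out["unit"].iloc[0] == "kg/person/year"

    def test_person_weighted_two_households(self):
        # equal totals, sizes 1 and 3: per-person = (2+2)/(1+3) x 365/14
        records = pd.DataFrame(
            {"year": [2006, 2006], "household_id": [0, 1],
             "item_code": ["IT_fish", "IT_fish"],
             "quantity_kg_fortnight": [2.0, 2.0], "household_size": [1.0, 3.0]}
        )
        out = aggregate_to_consumption(records, IDENTITY)
        assert out["quantity"].iloc[0] == pytest.approx(1.0 * 365 / 14)

    def test_empty_survey_gives_empty_table(self):
        empty = pd.DataFrame(
            columns=["year", "household_id", "item_code",
                     "quantity_kg_fortnight", "household_size"]
        )
        assert aggregate_to_consumption(empty, IDENTITY).empty

    def test_unmapped_item_code_listed(self):
        records = pd.DataFrame(
            {"year": [2006], "household_id": [0], "item_code": ["IT_mystery"],
             "quantity_kg_fortnight": [1.0], "household_size": [2.5]}
        )
        with pytest.raises(MappingError, match="IT_mystery"):
            aggregate_to_consumption(records, {"IT_fish": "fish"})


class TestRegimeSwitch:
    def test_mass_conserved_across_reassignment(self):
        """A classification switch moves mass between groups, never loses it."""
        switch = RegimeSwitch(2010, "grains", "fish", fraction=0.3)
        with_sw = TrendSpec("grains", 100.0, noise_cv=0.1, regime_switch=switch)
        base = TrendSpec("fish", 50.0, noise_cv=0.1)
        survey = generate_survey([with_sw, base], 200, YEARS, seed=5)
        cons = aggregate_to_consumption(survey, IDENTITY)
        no_sw = generate_survey(
            [TrendSpec("grains", 100.0, noise_cv=0.1), base], 200, YEARS, seed=5
        )
        cons_ref = aggregate_to_consumption(no_sw, IDENTITY)
        total = cons.groupby("year")["quantity"].sum()
        total_ref = cons_ref.groupby("year")["quantity"].sum()
        assert np.allclose(total, total_ref)

    def test_switch_moves_the_stated_fraction(self):
        switch = RegimeSwitch(2010, "grains", "fish", fraction=0.25)
        specs = [
            TrendSpec("grains", 100.0, regime_switch=switch),
            TrendSpec("fish", 40.0),
        ]
        cons = aggregate_to_consumption(generate_survey(specs, 10, YEARS, seed=0), IDENTITY)
        grains = level_g_day(cons, "grains")
        fish = level_g_day(cons, "fish")
        assert grains[2009] == pytest.approx(100.0)
        assert grains[2010] == pytest.approx(75.0)
        assert fish[2010] == pytest.approx(40.0 + 25.0)

    def test_switch_source_must_match_spec_group(self):
        with pytest.raises(ConfigurationError, match="source_group"):
            TrendSpec(
                "fish", 10.0,
                regime_switch=RegimeSwitch(2010, "grains", "fish", 0.5),
            )
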