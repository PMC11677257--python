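"""Joinpoint regression: exact recovery, grid search vs oracle, inference."""

import itertools

import numpy as np
import pytest

from dietfootprint import (
    AnnualSeries,
    ConfigurationError,
    ValidationError,
    apc_from_slope,
    fit_fixed_joinpoints,
    grid_search_joinpoints,
    select_model,
)
from dietfootprint.joinpoint import admissible_placements

from conftest import make_series


def two_segment_series(slope1=0.02, slope2=-0.03, kink=2010, years=range(2000, 2018)):
    years = np.asarray(list(years))
    log_y = np.where(
        years <= kink,
        1.0 + slope1 * (years - years[0]),
        1.0 + slope1 * (kink - years[0]) + slope2 * (years - kink),
    )
    return make_series(years, np.exp(log_y))


# ---------------------------------------------------------------------------
# Independent oracle: continuous piecewise-linear least squares built from a
# hat-function (knot-value) basis and interpolation — a different
# parameterisation from the hinge design used by the implementation.
# ---------------------------------------------------------------------------
def oracle_sse(years, log_values, joinpoints):
    knots = np.array([years[0], *joinpoints, years[-1]], dtype=float)
    basis = []
    for i in range(len(knots)):
        e = np.zeros(len(knots))
        e[i] = 1.0
        basis.append(np.interp(years.astype(float), knots, e))
    X = np.column_stack(basis)
    theta, _, _, _ = np.linalg.lstsq(X, log_values, rcond=None)
    resid = log_values - X @ theta
    return float(resid @ resid)


def oracle_best(series, k, min_segment=2):
    best = (np.inf, None)
    interior = [int(y) for y in series.years[1:-1]]
    for combo in itertools.combinations(interior, k):
        bounds = [series.years[0], *combo, series.years[-1]]
        if any(b - a - 1 < min_segment for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        sse = oracle_sse(series.years, series.log_values, combo)
        if sse < best[0] - 1e-12:
            best = (sse, combo)
    return best


class TestAnnualSeries:
    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValidationError, match="positive"):
            make_series([2006, 2007, 2008], [1.0, 0.0, 2.0])

    def test_rejects_missing_years(self):
        with pytest.raises(ValidationError, match="missing years"):
            make_series([2006, 2008, 2009], [1.0, 1.0, 1.0])


class TestFixedJoinpoints:
    def test_noiseless_two_segment_recovery(self):
        series = two_segment_series()
        fit = fit_fixed_joinpoints(series, [2010])
        assert fit.segment_slopes == pytest.approx([0.02, -0.03], abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_series_has_zero_slopes_and_apcs(self):
        series = make_series(range(2006, 2020), [7.0] * 14)
        fit = fit_fixed_joinpoints(series, [2012])
        assert np.allclose(fit.segment_slopes, 0.0, atol=1e-12)
        assert np.allclose(fit.apcs, 0.0, atol=1e-10)

    def test_fitted_mean_is_continuous_at_joinpoints(self, global_series):
        fit = fit_fixed_joinpoints(global_series, [2014, 2017])
        # rebuild the mean segment by segment from the reported slopes and
        # check the pieces meet at each joinpoint
        level = fit.coefficients[0]
        year = float(global_series.years[0])
        for (a, b), slope in zip(fit.segments, fit.segment_slopes):
            level_end = level + slope * (b - a)
            assert fit.predict_log(np.array([b]))[0] == pytest.approx(level_end, abs=1e-8)
            level, year = level_end, float(b)

    def test_segment_too_short_rejected(self, global_series):
        with pytest.raises(ValidationError, match="min_segment"):
            fit_fixed_joinpoints(global_series, [2007])

    def test_joinpoint_must_be_observed_interior_year(self, global_series):
        with pytest.raises(ValidationError, match="not an observed year"):
            fit_fixed_joinpoints(global_series, [1999])
        with pytest.raises(ValidationError, match="interior"):
            fit_fixed_joinpoints(global_series, [2006])


class TestGridSearch:
    def test_k0_matches_closed_form_ols(self, global_series):
        fit = grid_search_joinpoints(global_series, 0)
        slope = np.polyfit(
            global_series.years.astype(float), global_series.log_values, 1
        )[0]
        assert fit.segment_slopes[0] == pytest.approx(slope, abs=1e-12)

    def test_noiseless_kink_found_exactly(self):
        series = two_segment_series()
        fit = grid_search_joinpoints(series, 1)
        assert fit.joinpoints == (2010,)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_independent_enumeration_oracle(self, global_series, k):
        fit = grid_search_joinpoints(global_series, k)
        sse, combo = oracle_best(global_series, k)
        assert fit.sse == pytest.approx(sse, abs=1e-9)
        assert fit.joinpoints == combo

    def test_oracle_agreement_on_noisy_series(self):
        rng = np.random.default_rng(11)
        years = np.arange(2006, 2024)
        for _ in range(3):
            values = np.exp(0.5 + 0.01 * (years - 2006) + rng.normal(0, 0.05, len(years)))
            series = make_series(years, values)
            fit = grid_search_joinpoints(series, 2)
            sse, combo = oracle_best(series, 2)
            assert fit.sse == pytest.approx(sse, abs=1e-9)
            assert fit.joinpoints == combo

    def test_sse_monotone_in_k(self, global_series):
        sses = [grid_search_joinpoints(global_series, k).sse for k in range(4)]
        assert all(b <= a + 1e-12 for a, b in zip(sses, sses[1:]))

    def test_admissible_placements_respect_spacing(self):
        years = np.arange(2006, 2024)
        for combo in admissible_placements(years, 2, min_segment=2):
            bounds = [2006, *combo, 2023]
            assert all(b - a - 1 >= 2 for a, b in zip(bounds[:-1], bounds[1:]))
        assert (2014, 2017) in admissible_placements(years, 2, min_segment=2)


class TestApc:
    @pytest.mark.parametrize(
        "beta, expected", [(0.0, 0.0), (np.log(1.05), 5.0), (-0.0153, -1.52)]
    )
    def test_apc_from_slope(self, beta, expected):
        assert apc_from_slope(beta) == pytest.approx(expected, abs=5e-3)


class TestSelection:
    def test_nperm_zero_disallowed(self, global_series):
        with pytest.raises(ConfigurationError, match="n_perm"):
            select_model(global_series, k_max=1, n_perm=0, seed=1)

    def test_seed_required_for_permutation(self, global_series):
        with pytest.raises(ConfigurationError, match="seed"):
            select_model(global_series, k_max=1, n_perm=99)

    def test_infeasible_kmax_rejected(self):
        series = make_series(range(2006, 2012), np.linspace(1, 2, 6))
        with pytest.raises(ValidationError, match="infeasible"):
            select_model(series, k_max=3, n_perm=99, seed=1)

    def test_strong_kink_detected_and_reproducible(self):
        rng = np.random.default_rng(3)
        series = two_segment_series(0.04, -0.02, kink=2009, years=range(2000, 2018))
        noisy = make_series(
            series.years, series.values * np.exp(rng.normal(0, 0.005, len(series)))
        )
        fit = select_model(noisy, k_max=2, n_perm=199, seed=42)
        assert fit.n_joinpoints_selected >= 1
        again = select_model(noisy, k_max=2, n_perm=199, seed=42)
        assert again.joinpoints == fit.joinpoints
        assert again.selection_pvalues == fit.selection_pvalues

    def test_bic_selection_finds_clear_kink(self):
        series = two_segment_series(0.05, -0.05)
        fit = select_model(series, k_max=2, method="bic")
        assert fit.n_joinpoints_selected == 1
        assert fit.joinpoints == (2010,)
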