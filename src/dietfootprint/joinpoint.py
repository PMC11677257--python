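"""Joinpoint (segmented log-linear) trend analysis for annual series.

The model: for an annual series :math:`y_t > 0` observed at consecutive
calendar years, ``ln y_t`` is a continuous piecewise-linear function of
time with kinks ("joinpoints") at years :math:`\\tau_1 < \\dots < \\tau_k`:

.. math::

    \\ln y_t = \\beta_0 + \\beta_1 (t - t_0)
               + \\sum_{j=1}^{k} \\delta_j \\, (t - \\tau_j)_+ + \\varepsilon_t

with homoscedastic normal errors on the log scale.  The slope of segment
*j* is the cumulative sum :math:`\\beta_1 + \\delta_1 + \\dots + \\delta_j`,
and its annual percent change is :math:`\\mathrm{APC} = 100(e^{\\beta}-1)`.

Joinpoints are restricted to observed interior years, with at least
``min_segment`` observations strictly between consecutive boundaries
(series ends included).  For a fixed number of joinpoints the locations
are chosen by exhaustive grid search over admissible placements
(minimum SSE, ties broken by the lexicographically earliest year set).

The number of joinpoints is selected sequentially by permutation tests of
k vs k+1 joinpoints: residuals of the null (k-joinpoint) fit are permuted,
both models are re-fitted (including their grid searches) on each permuted
series, and the observed SSE-ratio statistic is compared with its
permutation distribution; the sequence of tests is Bonferroni-adjusted.
A BIC-based selection is available as a cheaper alternative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError

__all__ = [
    "AnnualSeries",
    "JoinpointFit",
    "apc_from_slope",
    "fit_fixed_joinpoints",
    "admissible_placements",
    "grid_search_joinpoints",
    "select_model",
]

DEFAULT_MIN_SEGMENT = 2


def apc_from_slope(beta: float) -> float:
    """Annual percent change implied by a log-scale slope: 100·(e^β − 1)."""
    return 100.0 * np.expm1(beta)


@dataclass(frozen=True)
class AnnualSeries:
    """A strictly positive annual series at consecutive calendar years."""

    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or years.shape != values.shape:
            raise ValidationError("years and values must be 1-D and equally long")
        if len(years) < 3:
            raise ValidationError("need at least 3 observations")
        if np.any(np.diff(years) <= 0):
            raise ValidationError("years must be strictly increasing")
        if np.any(np.diff(years) != 1):
            raise ValidationError("missing years inside the range are not supported")
        if np.any(values <= 0):
            bad = years[values <= 0]
            raise ValidationError(
                f"values must be positive for the log scale; offending year(s): {list(bad)}"
            )

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values)

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class JoinpointFit:
    """A fitted continuous piecewise log-linear model."""

    series: AnnualSeries = field(compare=False)
    joinpoints: tuple[int, ...]
    coefficients: np.ndarray  # (intercept, base slope, hinge increments...)
    segment_slopes: np.ndarray  # log-scale slope per segment
    slope_se: np.ndarray
    slope_p: np.ndarray
    sse: float
    fitted_log: np.ndarray = field(compare=False)
    n_joinpoints_selected: int | None = None
    selection_pvalues: tuple[float, ...] = ()

    @property
    def apcs(self) -> np.ndarray:
        """Annual percent change per segment, 100·(e^β − 1)."""
        return 100.0 * np.expm1(self.segment_slopes)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """(start_year, end_year) per segment."""
        bounds = [int(self.series.years[0]), *self.joinpoints, int(self.series.years[-1])]
        return list(zip(bounds[:-1], bounds[1:]))

    def predict_log(self, years: np.ndarray) -> np.ndarray:
        X = _hinge_design(np.asarray(years, dtype=float), self.series.years[0], self.joinpoints)
        return X @ self.coefficients


def _hinge_design(
    years: np.ndarray, origin: float, joinpoints: tuple[int, ...]
) -> np.ndarray:
    t = np.asarray(years, dtype=float) - origin
    cols = [np.ones_like(t), t]
    for tau in joinpoints:
        cols.append(np.maximum(0.0, t - (tau - origin)))
    return np.column_stack(cols)


def _check_placement(
    years: np.ndarray, joinpoints: tuple[int, ...], min_segment: int
) -> None:
    year_set = set(int(y) for y in years)
    for tau in joinpoints:
        if tau not in year_set:
            raise ValidationError(f"joinpoint {tau} is not an observed year")
        if tau in (years[0], years[-1]):
            raise ValidationError(f"joinpoint {tau} must be interior to the series")
    if any(b <= a for a, b in zip(joinpoints, joinpoints[1:])):
        raise ValidationError("joinpoints must be strictly increasing")
    bounds = [int(years[0]), *joinpoints, int(years[-1])]
    for a, b in zip(bounds[:-1], bounds[1:]):
        n_between = b - a - 1  # consecutive years: observations strictly between
        if n_between < min_segment:
            raise ValidationError(
                f"segment {a}–{b} has {n_between} interior observation(s); "
                f"min_segment is {min_segment}"
            )


def fit_fixed_joinpoints(
    series: AnnualSeries,
    joinpoints: list[int] | tuple[int, ...],
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> JoinpointFit:
    """Least-squares fit of ln(value) with kinks at the given years.

    Returns segment slopes with standard errors and two-sided p-values
    from t statistics on ``n − (2 + k)`` residual degrees of freedom.
    """
    joinpoints = tuple(int(t) for t in joinpoints)
    _check_placement(series.years, joinpoints, min_segment)
    y = series.log_values
    X = _hinge_design(series.years.astype(float), series.years[0], joinpoints)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    n, p = X.shape
    k = len(joinpoints)
    dof = n - p
    sigma2 = sse / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    # slope of segment j is a contrast c_j'beta with c_j = (0,1,1,...,1,0,..)
    slopes = np.cumsum(beta[1:])
    se = np.empty(k + 1)
    for j in range(k + 1):
        c = np.zeros(p)
        c[1 : 2 + j] = 1.0
        se[j] = np.sqrt(max(sigma2 * (c @ xtx_inv @ c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slopes / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof) if dof > 0 else np.full(k + 1, np.nan)
    return JoinpointFit(
        series=series,
        joinpoints=joinpoints,
        coefficients=beta,
        segment_slopes=slopes,
        slope_se=se,
        slope_p=pvals,
        sse=sse,
        fitted_log=X @ beta,
    )


def admissible_placements(
    years: np.ndarray, k: int, min_segment: int = DEFAULT_MIN_SEGMENT
) -> list[tuple[int, ...]]:
    """All placements of k joinpoints on observed interior years.

    A placement is admissible when every segment (including those bounded
    by the series ends) has at least ``min_segment`` observations strictly
    between its boundaries.  Returned in lexicographic year order.
    """
    if k < 0:
        raise ValidationError(f"k must be non-negative, got {k}")
    if k == 0:
        return [()]
    interior = [int(y) for y in years[1:-1]]
    out = []
    for combo in itertools.combinations(interior, k):
        bounds = [int(years[0]), *combo, int(years[-1])]
        if all(b - a - 1 >= min_segment for a, b in zip(bounds[:-1], bounds[1:])):
            out.append(combo)
    return out


def grid_search_joinpoints(
    series: AnnualSeries, k: int, min_segment: int = DEFAULT_MIN_SEGMENT
) -> JoinpointFit:
    """Best k-joinpoint fit by exhaustive search over admissible placements.

    Minimum SSE wins; exact ties go to the lexicographically earliest
    placement (placements are enumerated in that order and a strictly
    smaller SSE is required to displace the incumbent).
    """
    placements = admissible_placements(series.years, k, min_segment)
    if not placements:
        raise ValidationError(
            f"no admissible placement of {k} joinpoint(s) on {len(series)} "
            f"observations with min_segment={min_segment}"
        )
    best: JoinpointFit | None = None
    for placement in placements:
        fit = fit_fixed_joinpoints(series, placement, min_segment)
        if best is None or fit.sse < best.sse - 1e-12:
            best = fit
    assert best is not None
    return best


def _qr_factors(
    years: np.ndarray, placements: list[tuple[int, ...]]
) -> list[np.ndarray]:
    qs = []
    for placement in placements:
        X = _hinge_design(years.astype(float), years[0], placement)
        q, _ = np.linalg.qr(X)
        qs.append(q)
    return qs


def _min_sse_matrix(qs: list[np.ndarray], Y: np.ndarray) -> np.ndarray:
    """Columnwise minimum SSE over a family of designs, all columns at once."""
    total = np.einsum("ij,ij->j", Y, Y)
    best = np.full(Y.shape[1], np.inf)
    for q in qs:
        proj = q.T @ Y
        sse = total - np.einsum("ij,ij->j", proj, proj)
        np.minimum(best, sse, out=best)
    return best


def select_model(
    series: AnnualSeries,
    k_max: int,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    method: str = "permutation",
) -> JoinpointFit:
    """Choose the number of joinpoints (0..k_max) and return the best fit.

    ``method="permutation"`` (default): sequentially test k vs k+1
    joinpoints.  The statistic is the relative SSE drop
    ``(SSE_k − SSE_{k+1}) / SSE_{k+1}`` with each SSE minimised over its
    placement grid.  Its null distribution is built by permuting the
    residuals of the k-joinpoint fit around its fitted values and
    re-running both grid searches; the permutation p-value is
    ``(1 + #{T* ≥ T}) / (n_perm + 1)`` and each test is compared with
    ``alpha / k_max`` (Bonferroni over the sequence).  A seed is required.

    ``method="bic"``: minimise ``n·ln(SSE/n) + p·ln(n)`` with
    ``p = 2k + 2`` (each joinpoint spends one coefficient and one
    location).
    """
    if k_max < 0:
        raise ValidationError(f"k_max must be non-negative, got {k_max}")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if not admissible_placements(series.years, k_max, min_segment):
        raise ValidationError(
            f"k_max={k_max} is infeasible for {len(series)} observations "
            f"with min_segment={min_segment}"
        )

    fits = [grid_search_joinpoints(series, k, min_segment) for k in range(k_max + 1)]

    if method == "bic":
        n = len(series)
        bics = [
            n * np.log(f.sse / n if f.sse > 0 else np.finfo(float).tiny)
            + (2 * k + 2) * np.log(n)
            for k, f in enumerate(fits)
        ]
        k_sel = int(np.argmin(bics))
        return replace(fits[k_sel], n_joinpoints_selected=k_sel)
    if method != "permutation":
        raise ConfigurationError(f"unknown selection method {method!r}")
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be ≥ 1, got {n_perm}")
    if seed is None:
        raise ConfigurationError("permutation selection requires a seed")

    rng = np.random.default_rng(seed)
    years = series.years
    grids = [
        _qr_factors(years, admissible_placements(years, k, min_segment))
        for k in range(k_max + 1)
    ]
    threshold = alpha / k_max if k_max > 0 else alpha
    k_sel = 0
    pvalues: list[float] = []
    for k in range(k_max):
        null_fit = fits[k]
        alt_fit = fits[k + 1]
        if null_fit.sse <= 0:  # perfect null fit: nothing left to explain
            pvalues.append(1.0)
            break
        t_obs = (null_fit.sse - alt_fit.sse) / alt_fit.sse
        resid = series.log_values - null_fit.fitted_log
        perms = np.stack(
            [rng.permutation(len(resid)) for _ in range(n_perm)], axis=1
        )
        Y = null_fit.fitted_log[:, None] + resid[perms]
        sse_null = _min_sse_matrix(grids[k], Y)
        sse_alt = _min_sse_matrix(grids[k + 1], Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = (sse_null - sse_alt) / sse_alt
        pval = (1.0 + np.sum(t_perm >= t_obs)) / (n_perm + 1.0)
        pvalues.append(float(pval))
        if pval < threshold:
            k_sel = k + 1
        else:
            break
    return replace(
        fits[k_sel], n_joinpoints_selected=k_sel, selection_pvalues=tuple(pvalues)
    )
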