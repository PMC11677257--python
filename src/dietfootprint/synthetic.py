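"""Synthetic household budget survey generator.

Emulates the sampling design behind national expenditure surveys: each
year, households keep a 14-day purchase diary; annual per-person
consumption is the person-weighted total scaled from a fortnight to a
365-day year.  Group-level mean trends are piecewise log-linear in time —
a base level at the first year and an annual percent change (APC) per
segment, with kinks at configurable change points — so that downstream
trend estimators can be checked against known truth.

Household heterogeneity is multiplicative lognormal noise with a given
coefficient of variation, parameterised so the *mean* (not the median)
equals the trend expectation: purchase quantities are positive and
right-skewed.

An optional regime switch reassigns a fraction of one group's purchases to
another group from a stated year onwards, mimicking the discontinuity a
classification change (such as the 2016 COICOP→ECOICOP revision)
introduces into item-coded series.  The reassignment conserves total mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MappingError, ValidationError
from .units import DAYS_PER_YEAR

__all__ = [
    "DIARY_DAYS",
    "RegimeSwitch",
    "TrendSpec",
    "SyntheticSurvey",
    "generate_survey",
    "aggregate_to_consumption",
    "item_code",
]

#: Length of each household's expenditure diary, days.
DIARY_DAYS = 14

#: Default persons per household; the survey reports per-person amounts only.
DEFAULT_HOUSEHOLD_SIZE = 2.5


def item_code(group: str) -> str:
    """Survey item code carrying a group's purchases."""
    return f"IT_{group}"


@dataclass(frozen=True)
class RegimeSwitch:
    """Persistent reassignment of purchases between groups from a year on."""

    year: int
    source_group: str
    target_group: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"switch fraction must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class TrendSpec:
    """Piecewise log-linear mean trend for one food group.

    ``base_level`` is the expected per-person daily consumption
    (g/person/day) in the first survey year; ``segment_apcs`` are annual
    percent changes per segment, with segments delimited by
    ``change_points`` (strictly increasing years interior to the range).
    """

    group: str
    base_level: float
    segment_apcs: tuple[float, ...] = (0.0,)
    change_points: tuple[int, ...] = ()
    noise_cv: float = 0.0
    regime_switch: RegimeSwitch | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment_apcs", tuple(self.segment_apcs))
        object.__setattr__(self, "change_points", tuple(self.change_points))
        if self.base_level <= 0:
            raise ValidationError(f"base_level must be positive, got {self.base_level}")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be non-negative, got {self.noise_cv}")
        if any(b <= a for a, b in zip(self.change_points, self.change_points[1:])):
            raise ValidationError("change_points must be strictly increasing")
        if len(self.segment_apcs) != len(self.change_points) + 1:
            raise ValidationError(
                f"need {len(self.change_points) + 1} segment APCs for "
                f"{len(self.change_points)} change points, got {len(self.segment_apcs)}"
            )
        if self.regime_switch is not None and self.regime_switch.source_group != self.group:
            raise ConfigurationError(
                "regime_switch.source_group must equal the spec's group"
            )

    def check_years(self, years: range) -> None:
        for cp in self.change_points:
            if not (years[0] < cp < years[-1]):
                raise ValidationError(
                    f"change point {cp} outside the interior of {years[0]}–{years[-1]}"
                )

    def expected_levels(self, years: range) -> np.ndarray:
        """Expected g/person/day per year: base·∏(1+APC_j/100)^(years in j)."""
        self.check_years(years)
        growth = np.empty(len(years) - 1)
        for i, y in enumerate(years[:-1]):
            seg = int(np.searchsorted(np.asarray(self.change_points), y, side="right"))
            growth[i] = 1.0 + self.segment_apcs[seg] / 100.0
        return self.base_level * np.concatenate([[1.0], np.cumprod(growth)])


@dataclass(frozen=True)
class SyntheticSurvey:
    """Household-level 14-day purchase records.

    ``records`` columns: year, household_id, item_code,
    quantity_kg_fortnight, household_size.  Each household appears in one
    diary per year.
    """

    records: pd.DataFrame
    household_size: float
    seed: int
    specs: tuple[TrendSpec, ...] = field(default=(), compare=False)


def generate_survey(
    specs: list[TrendSpec] | tuple[TrendSpec, ...],
    n_households: int,
    years: range,
    seed: int,
    household_size: float = DEFAULT_HOUSEHOLD_SIZE,
) -> SyntheticSurvey:
    """Simulate 14-day purchase diaries with known group-level trends.

    The expected aggregate of group *g* in year *y* equals the TrendSpec
    trajectory exactly; household quantities are lognormal around it with
    the spec's coefficient of variation (mean-preserving).  Identical
    seeds reproduce identical surveys bit for bit.
    """
    if n_households < 1:
        raise ConfigurationError(f"n_households must be ≥ 1, got {n_households}")
    if household_size <= 0:
        raise ConfigurationError(f"household_size must be positive, got {household_size}")
    groups = [s.group for s in specs]
    if len(set(groups)) != len(groups):
        dup = sorted({g for g in groups if groups.count(g) > 1})
        raise ConfigurationError(f"overlapping TrendSpecs for group(s): {dup}")

    rng = np.random.default_rng(seed)
    frames = []
    hh_ids = np.arange(n_households)
    for spec in specs:
        levels = spec.expected_levels(years)
        for year, level in zip(years, levels):
            # expected household purchase over the diary fortnight, kg
            mean_kg = level * household_size * DIARY_DAYS / 1000.0
            if spec.noise_cv > 0:
                sigma2 = np.log1p(spec.noise_cv**2)
                noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n_households)
            else:
                noise = np.ones(n_households)
            qty = mean_kg * noise
            code = item_code(spec.group)
            sw = spec.regime_switch
            if sw is not None and year >= sw.year and sw.fraction > 0:
                frames.append(
                    pd.DataFrame(
                        {
                            "year": year,
                            "household_id": hh_ids,
                            "item_code": item_code(sw.target_group),
                            "quantity_kg_fortnight": qty * sw.fraction,
                        }
                    )
                )
                qty = qty * (1.0 - sw.fraction)
            frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "household_id": hh_ids,
                        "item_code": code,
                        "quantity_kg_fortnight": qty,
                    }
                )
            )
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=["year", "household_id", "item_code", "quantity_kg_fortnight"]
        )
    records["household_size"] = household_size
    records = records.sort_values(
        ["year", "household_id", "item_code"], kind="stable"
    ).reset_index(drop=True)
    return SyntheticSurvey(records, household_size, seed, tuple(specs))


def aggregate_to_consumption(
    survey: SyntheticSurvey | pd.DataFrame,
    item_to_group: dict[str, str],
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Aggregate diaries to per-group kg/person/year.

    Per (year, group): total fortnight kg over households ÷ total persons,
    scaled by days_per_year/14.  Returns a validated-shape consumption
    table (``year,item,quantity,unit``) with unit kg/person/year.
    """
    records = survey.records if isinstance(survey, SyntheticSurvey) else survey
    if records.empty:
        return pd.DataFrame(columns=["year", "item", "quantity", "unit"])
    unmapped = sorted(set(records["item_code"]) - set(item_to_group))
    if unmapped:
        raise MappingError(f"no group mapping for item code(s): {unmapped}")
    persons = (
        records.drop_duplicates(["year", "household_id"])
        .groupby("year")["household_size"]
        .sum()
    )
    grouped = records.copy()
    grouped["group"] = grouped["item_code"].map(item_to_group)
    totals = grouped.groupby(["year", "group"], as_index=False)[
        "quantity_kg_fortnight"
    ].sum()
    totals["quantity"] = (
        totals["quantity_kg_fortnight"]
        / totals["year"].map(persons)
        * (days_per_year / DIARY_DAYS)
    )
    out = totals[["year", "group"]].rename(columns={"group": "item"})
    out["quantity"] = totals["quantity"]
    out["unit"] = "kg/person/year"
    return out.sort_values(["year", "item"]).reset_index(drop=True)
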