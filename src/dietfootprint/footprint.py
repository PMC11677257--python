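"""Dietary greenhouse-gas footprint accounting.

Each food's emission is its daily intake (g/person/day) times a life-cycle
emission coefficient (g CO₂-eq per g of food).  Per-group footprints are
sums over the foods mapped to the group; the global footprint is the sum
over groups, and reporting super-group rows (RM_FS_D_F, Pou_Eggs, Others)
are sums over their member groups.  Percent changes between two years are
always computed on unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MappingError, ValidationError
from .taxonomy import DEFAULT_TAXONOMY, GLOBAL, FoodGroupTaxonomy

__all__ = [
    "ChangeSummary",
    "food_emission",
    "compute_footprint",
    "total_footprint",
    "percent_change",
]


@dataclass(frozen=True)
class ChangeSummary:
    """Percent change of one series between a start and an end year."""

    label: str
    start_year: int
    end_year: int
    start_value: float
    end_value: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.end_value - self.start_value) / self.start_value


def food_emission(intake_g_day: float, factor_gco2e_per_g: float) -> float:
    """GHG emission of one food: intake × emission coefficient (exact)."""
    if intake_g_day < 0:
        raise ValidationError(f"intake must be non-negative, got {intake_g_day}")
    if factor_gco2e_per_g <= 0:
        raise ValidationError(f"emission factor must be positive, got {factor_gco2e_per_g}")
    return intake_g_day * factor_gco2e_per_g


def compute_footprint(
    daily_intake: pd.DataFrame,
    factors: pd.DataFrame,
    food_to_group: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-food (or per-group) GHG emissions from daily intake.

    Parameters
    ----------
    daily_intake
        ``year,food,grams_per_person_day`` table.
    factors
        ``food,gco2e_per_g`` emission-factor table; every food in the
        intake must have exactly one factor.
    food_to_group
        Optional food→group map; when given, per-food emissions are summed
        into a ``year,group,gco2e_per_day`` table, otherwise the table is
        returned per food under the same schema (``group`` column holds
        food names).
    """
    missing = sorted(set(daily_intake["food"]) - set(factors["food"]))
    if missing:
        raise MappingError(f"no emission factor for food(s): {missing}")
    merged = daily_intake.merge(factors, on="food", how="left")
    merged["gco2e_per_day"] = merged["grams_per_person_day"] * merged["gco2e_per_g"]
    if food_to_group is not None:
        unmapped = sorted(set(merged["food"]) - set(food_to_group))
        if unmapped:
            raise MappingError(f"no group for food(s): {unmapped}")
        merged["group"] = merged["food"].map(food_to_group)
    else:
        merged["group"] = merged["food"]
    return (
        merged.groupby(["year", "group"], as_index=False)["gco2e_per_day"]
        .sum()
        .sort_values(["year", "group"])
        .reset_index(drop=True)
    )


def total_footprint(
    per_group: pd.DataFrame, taxonomy: FoodGroupTaxonomy = DEFAULT_TAXONOMY
) -> pd.DataFrame:
    """Append per-year super-group and global rows to a per-group table.

    ``per_group`` must hold one row per (year, group), groups drawn from
    the taxonomy.  The output contains the original rows plus, per year,
    one row per super-group (sum of member groups) and a ``global`` row
    (sum of all groups).
    """
    for g in per_group["group"].unique():
        taxonomy.check_group(g)
    dup = per_group.duplicated(subset=["year", "group"])
    if dup.any():
        raise ValidationError(
            f"footprint table has duplicate (year, group) rows: "
            f"{list(per_group.loc[dup, ['year', 'group']].itertuples(index=False, name=None))[:10]}"
        )
    extra = []
    by_year = per_group.groupby("year")
    for year, block in by_year:
        sg = block["group"].map(taxonomy.super_group_of)
        sums = block.groupby(sg.values)["gco2e_per_day"].sum()
        for name in taxonomy.super_groups:
            if name in sums.index:
                extra.append((year, name, float(sums[name])))
        extra.append((year, GLOBAL, float(block["gco2e_per_day"].sum())))
    extra_df = pd.DataFrame(extra, columns=["year", "group", "gco2e_per_day"])
    return pd.concat([per_group, extra_df], ignore_index=True)


def percent_change(
    footprint: pd.DataFrame, label: str, start_year: int, end_year: int
) -> ChangeSummary:
    """Percent change of one group's series between two years.

    Computed on unrounded values; display rounding (one decimal in the
    reporting layer) never feeds back into the statistic.
    """
    series = footprint[footprint["group"] == label].set_index("year")["gco2e_per_day"]
    for year in (start_year, end_year):
        if year not in series.index:
            raise ValidationError(f"year {year} absent from series {label!r}")
    start, end = float(series[start_year]), float(series[end_year])
    if start == 0:
        raise ValidationError(
            f"percent change undefined: {label!r} is 0 in start year {start_year}"
        )
    return ChangeSummary(label, start_year, end_year, start, end)
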