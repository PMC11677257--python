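"""Food-group taxonomy and reporting super-groups.

The pipeline works on 14 food groups (red meat, fish, seafood, dairy, fats,
poultry, eggs, grains, vegetables, fruits, alcohol, potatoes, legumes,
sugar).  For reporting, groups are aggregated into three super-groups:

* ``RM_FS_D_F`` — red meat, fish and seafood, dairy, and fats: the
  animal-sourced groups that dominate the dietary carbon footprint;
* ``Pou_Eggs`` — poultry and eggs;
* ``Others`` — vegetables, fruits, legumes, potatoes, grains, sugar and
  alcohol.

The three super-groups partition the groups exactly; the taxonomy validates
this at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import TaxonomyError

__all__ = ["FoodGroupTaxonomy", "DEFAULT_TAXONOMY", "GLOBAL"]

#: Identifier of the all-groups total row in footprint tables.
GLOBAL = "global"


@dataclass(frozen=True)
class FoodGroupTaxonomy:
    """Ordered food groups, display labels and super-group partition."""

    groups: tuple[str, ...]
    super_groups: Mapping[str, frozenset[str]]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for name, members in self.super_groups.items():
            overlap = union & set(members)
            if overlap:
                raise TaxonomyError(
                    f"groups {sorted(overlap)} belong to more than one "
                    f"super-group (while adding {name!r})"
                )
            union |= set(members)
        missing = set(self.groups) - union
        extra = union - set(self.groups)
        if missing or extra:
            raise TaxonomyError(
                f"super-groups do not partition the groups: "
                f"uncovered={sorted(missing)}, unknown={sorted(extra)}"
            )

    def super_group_of(self, group: str) -> str:
        for name, members in self.super_groups.items():
            if group in members:
                return name
        raise TaxonomyError(f"unknown food group: {group!r}")

    def label(self, group: str) -> str:
        return self.labels.get(group, group.replace("_", " ").title())

    def check_group(self, group: str) -> None:
        if group not in self.groups:
            raise TaxonomyError(f"unknown food group: {group!r}")


DEFAULT_TAXONOMY = FoodGroupTaxonomy(
    groups=(
        "red_meat",
        "fish",
        "seafood",
        "dairy",
        "fats",
        "poultry",
        "eggs",
        "grains",
        "vegetables",
        "fruits",
        "alcohol",
        "potatoes",
        "legumes",
        "sugar",
    ),
    super_groups={
        "RM_FS_D_F": frozenset({"red_meat", "fish", "seafood", "dairy", "fats"}),
        "Pou_Eggs": frozenset({"poultry", "eggs"}),
        "Others": frozenset(
            {"vegetables", "fruits", "legumes", "potatoes", "grains", "sugar", "alcohol"}
        ),
    },
    labels={"red_meat": "Red Meat", "fish": "Fish", "seafood": "Seafood"},
)
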