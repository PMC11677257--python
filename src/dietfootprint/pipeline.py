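"""End-to-end pipeline: consumption → footprint → diet score → trends.

One config drives every stage and all outputs are plain CSV/JSON written
to an output directory, with a manifest recording the package version,
the seed and a hash of the resolved configuration so that runs are
reproducible byte for byte.

The footprint stage has two entry points: a per-group footprint can be
computed from consumption × emission factors (via the basket mapping), or
a ready-made per-group footprint table can be supplied directly — useful
when published emission series are analysed without access to the
underlying coefficients.  Super-group and global rows are always
recomputed from the per-group rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, StageError, ValidationError
from .footprint import compute_footprint, percent_change, total_footprint
from .joinpoint import AnnualSeries, select_model
from .meddiet import SCORE_BY_NAME, score_by_year
from .tables import (
    read_consumption_table,
    read_emission_factors,
    read_footprint_table,
    read_mapping,
    write_results,
)
from .taxonomy import DEFAULT_TAXONOMY, GLOBAL, FoodGroupTaxonomy
from .units import (
    DEFAULT_ALCOHOL_DENSITY,
    DEFAULT_EGG_MASS_G,
    DAYS_PER_YEAR,
    consumption_to_daily_intake,
    disaggregate,
)

__all__ = ["PipelineConfig", "run_pipeline", "share_change_series"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, constants and trend settings for one pipeline run."""

    out_dir: str
    consumption_path: str | None = None
    factors_path: str | None = None
    mapping_path: str | None = None
    footprint_path: str | None = None
    food_groups_path: str | None = None
    score_config: str = "default"
    days_per_year: float = DAYS_PER_YEAR
    egg_mass_g: float = DEFAULT_EGG_MASS_G
    alcohol_density: float = DEFAULT_ALCOHOL_DENSITY
    k_max: int = 3
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("days_per_year", "egg_mass_g", "alcohol_density"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.footprint_path is None and self.consumption_path is None:
            raise ConfigurationError(
                "config needs consumption_path (+factors_path) or footprint_path"
            )
        if self.score_config not in SCORE_BY_NAME:
            raise ConfigurationError(
                f"unknown score_config {self.score_config!r}; "
                f"expected one of {sorted(SCORE_BY_NAME)}"
            )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Load YAML or JSON config; relative paths resolve against it."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("consumption_path", "factors_path", "mapping_path",
                    "footprint_path", "food_groups_path", "out_dir"):
            if raw.get(key) and not os.path.isabs(raw[key]):
                raw[key] = str((path.parent / raw[key]).resolve())
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def share_change_series(footprint: pd.DataFrame, base_year: int) -> pd.DataFrame:
    """Super-group shares of global GHG and their change since a base year.

    Requires super-group and global rows (append them with
    :func:`total_footprint` first).  Shares per year sum to 1; the change
    column is the share minus its base-year value, so the base year maps
    to 0 for every super-group.
    """
    groups = set(footprint["group"])
    super_names = [g for g in DEFAULT_TAXONOMY.super_groups if g in groups]
    if GLOBAL not in groups or not super_names:
        raise ValidationError("footprint table lacks super-group/global rows")
    wide = footprint.pivot_table(
        index="year", columns="group", values="gco2e_per_day"
    )
    if base_year not in wide.index:
        raise ValidationError(f"base year {base_year} absent from footprint table")
    shares = wide[super_names].div(wide[GLOBAL], axis=0)
    change = shares - shares.loc[base_year]
    out = shares.reset_index().melt(
        id_vars="year", var_name="super_group", value_name="share"
    )
    chg = change.reset_index().melt(
        id_vars="year", var_name="super_group", value_name="change_vs_base"
    )
    out["change_vs_base"] = chg["change_vs_base"]
    return out.sort_values(["year", "super_group"]).reset_index(drop=True)


def _footprint_stage(
    config: PipelineConfig, taxonomy: FoodGroupTaxonomy
) -> pd.DataFrame:
    if config.footprint_path is not None:
        fp = read_footprint_table(config.footprint_path)
        drop = {GLOBAL, *taxonomy.super_groups}
        return fp[~fp["group"].isin(drop)].reset_index(drop=True)
    if config.factors_path is None:
        raise ConfigurationError("factors_path required to compute a footprint")
    consumption = read_consumption_table(config.consumption_path)
    intake = consumption_to_daily_intake(
        consumption, config.egg_mass_g, config.days_per_year
    )
    if config.mapping_path is not None:
        mapping = read_mapping(config.mapping_path)
        intake = disaggregate(intake, mapping)
    else:
        intake = intake.rename(columns={"item": "food"})
    factors = read_emission_factors(config.factors_path)
    if config.food_groups_path is not None:
        fg = pd.read_csv(config.food_groups_path)
        food_to_group = dict(zip(fg["food"], fg["group"]))
    else:
        food_to_group = {f: f for f in intake["food"].unique()}
    return compute_footprint(intake, factors, food_to_group)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the paper-style artifact set.

    Writes, under ``config.out_dir``: a wide consumption matrix, the
    per-group + super-group + global footprint table, annual Dietary
    Score results, joinpoint trend fits for the global and the three
    super-group series, first→last-year percent changes, super-group
    share series, and ``manifest.json``.  Returns the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    taxonomy = DEFAULT_TAXONOMY
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str, precision: int | None) -> None:
        write_results(df, out_dir / name, precision=precision)
        written.append(name)

    # --- consumption ---------------------------------------------------
    consumption = None
    if config.consumption_path is not None:
        try:
            consumption = read_consumption_table(config.consumption_path)
            wide = consumption.pivot_table(
                index="year", columns="item", values="quantity"
            ).reset_index()
            emit(wide, "consumption_matrix.csv", precision=1)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("consumption", str(exc)) from exc

    # --- footprint ------------------------------------------------------
    try:
        per_group = _footprint_stage(config, taxonomy)
        fp = total_footprint(per_group, taxonomy)
        emit(fp.sort_values(["year", "group"]), "footprint.csv", precision=1)
    except Exception as exc:
        raise StageError("footprint", str(exc)) from exc

    # --- diet score -----------------------------------------------------
    scores = None
    if consumption is not None:
        try:
            scores = score_by_year(consumption, SCORE_BY_NAME[config.score_config])
            emit(scores, "dietary_scores.csv", precision=None)
        except Exception as exc:
            raise StageError("score", str(exc)) from exc

    # --- trends ---------------------------------------------------------
    trend_labels = [GLOBAL, *taxonomy.super_groups]
    try:
        seg_rows = []
        summaries = {}
        for i, label in enumerate(trend_labels):
            block = fp[fp["group"] == label].sort_values("year")
            series = AnnualSeries(
                block["year"].to_numpy(), block["gco2e_per_day"].to_numpy(), label
            )
            fit = select_model(
                series,
                k_max=config.k_max,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=config.seed + i,
            )
            for (a, b), slope, apc, p in zip(
                fit.segments, fit.segment_slopes, fit.apcs, fit.slope_p
            ):
                seg_rows.append(
                    {
                        "series": label,
                        "start_year": a,
                        "end_year": b,
                        "slope": round(float(slope), 6),
                        "apc": round(float(apc), 2),
                        "p": round(float(p), 4),
                    }
                )
            summaries[label] = {
                "joinpoints": list(fit.joinpoints),
                "n_joinpoints_selected": fit.n_joinpoints_selected,
                "selection_pvalues": list(fit.selection_pvalues),
                "apcs": [round(float(a), 2) for a in fit.apcs],
                "sse": fit.sse,
            }
        emit(pd.DataFrame(seg_rows), "trend_segments.csv", precision=None)
        with open(out_dir / "trend_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        written.append("trend_summary.json")
    except Exception as exc:
        raise StageError("trends", str(exc)) from exc

    # --- report ---------------------------------------------------------
    try:
        first, last = int(fp["year"].min()), int(fp["year"].max())
        changes = []
        for label in trend_labels:
            cs = percent_change(fp, label, first, last)
            changes.append(
                {
                    "label": cs.label,
                    "start_year": cs.start_year,
                    "end_year": cs.end_year,
                    "start_value": round(cs.start_value, 1),
                    "end_value": round(cs.end_value, 1),
                    "percent_change": round(cs.percent_change, 1),
                }
            )
        emit(pd.DataFrame(changes), "percent_changes.csv", precision=None)
        shares = share_change_series(fp, base_year=first)
        emit(shares, "shares.csv", precision=4)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    manifest = {
        "package": "dietfootprint",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": dataclasses.asdict(config),
        "outputs": written,
        "global_percent_change": changes[0]["percent_change"],
        "dietary_score_range": (
            [int(scores["total"].min()), int(scores["total"].max())]
            if scores is not None
            else None
        ),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
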