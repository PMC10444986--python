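"""Species proportional contributions to resource provision and insect visits.

Because a single 1 m² plot rarely captures the whole flowering community,
contributions are computed at the river-site scale by pooling all plots and
survey occasions in a period (calendar month, or study year), then dividing
each species' pooled total by the grand total:

    p_i = Σ_plots,occasions x_i / Σ_species Σ_plots,occasions x .

Annual contributions pool raw year totals — they are *not* averages of
monthly proportions — so proportions reflect gross provision over the year.

Measures: ``sugar`` and ``pollen`` (area-based availability of measured
species), ``visits_all`` and per-group ``visits_bee_wasp`` /
``visits_hoverfly`` / ``visits_butterfly``. Visit contributions include
species without resource profiles; resource contributions never do.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import WILD_GROUPS, YearBoundaries, assign_periods, filter_visits

logger = logging.getLogger(__name__)

__all__ = ["MEASURES", "contribution_table", "resource_contributions", "visit_contributions"]

MEASURES = (
    "sugar", "pollen", "visits_all",
    "visits_bee_wasp", "visits_hoverfly", "visits_butterfly",
)


def _proportions(
    df: pd.DataFrame, value_col: str, period_col: str, measure: str
) -> pd.DataFrame:
    """Pool `value_col` per (site, period, species) and normalize per (site, period)."""
    pooled = (
        df.groupby(["site", period_col, "species_id"], observed=True)[value_col]
        .sum()
        .reset_index()
    )
    grand = pooled.groupby(["site", period_col], observed=True)[value_col].transform("sum")
    zero = grand <= 0
    if zero.any():
        empties = pooled.loc[zero, ["site", period_col]].drop_duplicates()
        logger.info(
            "%s: %d (site, period) cells with zero grand total dropped", measure, len(empties)
        )
    pooled = pooled.loc[~zero].copy()
    pooled["proportion"] = pooled[value_col] / grand[~zero]
    pooled["measure"] = measure
    pooled = pooled.rename(columns={period_col: "period"})
    return pooled[["site", "period", "measure", "species_id", "proportion"]]


def _with_periods(df: pd.DataFrame, boundaries: YearBoundaries | None) -> pd.DataFrame:
    periods = assign_periods(df["date"], boundaries)
    out = df.copy()
    out["study_year"] = periods["study_year"].to_numpy()
    out["month_label"] = periods["month_label"].to_numpy()
    return out


def resource_contributions(
    per_species_avail: pd.DataFrame,
    period: str = "month",
    boundaries: YearBoundaries | None = None,
) -> pd.DataFrame:
    """Species shares of pooled sugar and pollen availability.

    `per_species_avail` is the long table from
    :func:`florivis.availability.per_species_availability`; rows with NaN
    (unmeasured species) do not enter the pooled totals.
    """
    period_col = {"month": "month_label", "year": "study_year"}[period]
    df = _with_periods(per_species_avail, boundaries)
    parts = []
    for measure, col in [("sugar", "sugar_ug_m2"), ("pollen", "pollen_ul_m2")]:
        measured = df.loc[df[col].notna()]
        parts.append(_proportions(measured, col, period_col, measure))
    return pd.concat(parts, ignore_index=True)


def visit_contributions(
    visits: pd.DataFrame,
    period: str = "month",
    boundaries: YearBoundaries | None = None,
) -> pd.DataFrame:
    """Species shares of wild-insect visits, per group and pooled.

    Applies the wild-group filter first (idempotent), so managed honeybees
    and scarce taxa never enter the denominators.
    """
    period_col = {"month": "month_label", "year": "study_year"}[period]
    wild = filter_visits(visits)
    df = _with_periods(wild, boundaries)
    parts = [_proportions(df, "count", period_col, "visits_all")]
    for group in WILD_GROUPS:
        sub = df.loc[df["insect_group"] == group]
        if len(sub):
            parts.append(_proportions(sub, "count", period_col, f"visits_{group}"))
        else:
            logger.info("visit_contributions: no %s visits recorded", group)
    return pd.concat(parts, ignore_index=True)


def contribution_table(
    per_species_avail: pd.DataFrame,
    visits: pd.DataFrame,
    period: str = "month",
    boundaries: YearBoundaries | None = None,
) -> pd.DataFrame:
    """All six measures in one table (site, period, measure, species_id, proportion)."""
    return pd.concat(
        [
            resource_contributions(per_species_avail, period, boundaries),
            visit_contributions(visits, period, boundaries),
        ],
        ignore_index=True,
    )
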