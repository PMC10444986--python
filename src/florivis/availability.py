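"""Area-based floral resource availability per 1 m² plot and occasion.

A species' contribution to a plot is its open floral-unit count times its
per-flower species mean (sugar µg, pollen µL); plot totals sum the measured
species. A species unmeasured for one resource is excluded from that
resource's total only — exclusion is tracked, never silently zeroed.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["per_species_availability", "plot_availability"]


def per_species_availability(
    counts: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Long-format per-species availability.

    One row per floral count record, with ``sugar_ug_m2`` and
    ``pollen_ul_m2`` (NaN where the species is unmeasured for that
    resource) and boolean ``sugar_measured`` / ``pollen_measured`` flags.
    """
    df = counts.merge(
        profiles[["species_id", "mean_sugar_ug", "mean_pollen_ul"]],
        on="species_id", how="left",
    )
    df["sugar_measured"] = df["mean_sugar_ug"].notna()
    df["pollen_measured"] = df["mean_pollen_ul"].notna()
    df["sugar_ug_m2"] = df["floral_units"] * df["mean_sugar_ug"]
    df["pollen_ul_m2"] = df["floral_units"] * df["mean_pollen_ul"]
    return df.drop(columns=["mean_sugar_ug", "mean_pollen_ul"])


def plot_availability(
    counts: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot/occasion resource totals and the per-species long table.

    Returns ``(totals, per_species)``. ``totals`` has one row per
    (site, date, plot_id) present in `counts`, with ``sugar_ug_m2`` and
    ``pollen_ul_m2`` summed over measured species and
    ``n_species_unmeasured_sugar`` / ``_pollen`` exclusion tallies.
    """
    long = per_species_availability(counts, profiles)
    key = ["site", "date", "plot_id"]
    grouped = long.groupby(key)
    totals = grouped.agg(
        sugar_ug_m2=("sugar_ug_m2", lambda s: s.sum(skipna=True)),
        pollen_ul_m2=("pollen_ul_m2", lambda s: s.sum(skipna=True)),
        n_species=("species_id", "nunique"),
        n_species_unmeasured_sugar=("sugar_measured", lambda s: int((~s).sum())),
        n_species_unmeasured_pollen=("pollen_measured", lambda s: int((~s).sum())),
    ).reset_index()
    n_excl = int(totals["n_species_unmeasured_sugar"].sum())
    if n_excl:
        logger.info("plot_availability: %d species-rows excluded from sugar totals", n_excl)
    return totals, long
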