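"""Reading, validation and period-indexing of the survey tables.

Three tidy CSV tables feed the pipeline:

``species.csv``
    ``species_id,origin,has_nectaries,floral_unit_type`` — one row per
    flowering species, with its origin (``alien``/``native``) and the floral
    unit used for counting (``head`` for composites and clovers, ``flower``
    otherwise).
``floral_counts.csv``
    ``site,date,plot_id,species_id,floral_units`` — open floral units of one
    species in one 1 m² plot on one survey occasion.
``visits.csv``
    ``site,date,plot_id,species_id,insect_group,count`` — insect visits per
    plot and occasion, pre-summed over the two 10-min observation rounds.

All files are UTF-8, comma-separated, with a header row and ISO-8601 dates.
Missing survey occasions (e.g. mowing gaps) are absent rows, never zeros.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "YearBoundaries",
    "ORIGINS",
    "FLORAL_UNIT_TYPES",
    "INSECT_GROUPS",
    "WILD_GROUPS",
    "read_species",
    "read_floral_counts",
    "read_visits",
    "write_table",
    "filter_visits",
    "visit_totals_by_group",
    "assign_periods",
    "validate_dataset",
]

ORIGINS = frozenset({"alien", "native"})
FLORAL_UNIT_TYPES = frozenset({"flower", "head"})
#: closed set of visitor categories recorded in the field
INSECT_GROUPS = frozenset(
    {"bee_wasp", "hoverfly", "butterfly", "honeybee", "coleoptera", "hemiptera"}
)
#: the three wild pollinator groups retained for analysis; honeybees are
#: excluded as a managed species, Coleoptera/Hemiptera for small numbers
WILD_GROUPS = ("bee_wasp", "hoverfly", "butterfly")

SPECIES_COLUMNS = ["species_id", "origin", "has_nectaries", "floral_unit_type"]
FLORAL_COLUMNS = ["site", "date", "plot_id", "species_id", "floral_units"]
VISIT_COLUMNS = ["site", "date", "plot_id", "species_id", "insect_group", "count"]


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class ValidationError(ValueError):
    """A table violates a record-level invariant."""


@dataclass(frozen=True)
class YearBoundaries:
    """Half-open study-year intervals ``[year1_start, year2_start)`` and
    ``[year2_start, end)``.

    Defaults are the study's survey window: year 1 from 21 April 2018 to
    13 April 2019, year 2 from 14 April 2019 to 4 April 2020.
    """

    year1_start: dt.date = dt.date(2018, 4, 21)
    year2_start: dt.date = dt.date(2019, 4, 14)
    end: dt.date = dt.date(2020, 4, 5)

    def __post_init__(self) -> None:
        if not (self.year1_start < self.year2_start < self.end):
            raise ValueError("year boundaries must be strictly increasing")


def _check_columns(df: pd.DataFrame, expected: list[str], path: object) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; expected {expected}")


def _parse_dates(df: pd.DataFrame, path: object) -> pd.Series:
    try:
        parsed = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: column 'date' is not ISO-8601: {exc}") from exc
    return parsed.dt.date


def read_species(path: str | Path) -> pd.DataFrame:
    """Read and validate the species metadata table."""
    df = pd.read_csv(path)
    _check_columns(df, SPECIES_COLUMNS, path)
    df = df[SPECIES_COLUMNS].copy()
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"{path}: duplicate species_id {dups}")
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid origin at row(s) {df.index[bad].tolist()}"
        )
    bad = ~df["floral_unit_type"].isin(FLORAL_UNIT_TYPES)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid floral_unit_type at row(s) {df.index[bad].tolist()}"
        )
    df["has_nectaries"] = df["has_nectaries"].astype(bool)
    logger.info("read %d species from %s", len(df), path)
    return df


def _check_species_known(df: pd.DataFrame, species: pd.DataFrame, path: object) -> None:
    known = set(species["species_id"])
    unknown = sorted(set(df["species_id"]) - known)
    if unknown:
        raise ValidationError(
            f"{path}: species_id not in species table: {unknown}"
        )


def read_floral_counts(path: str | Path, species: pd.DataFrame) -> pd.DataFrame:
    """Read per-plot open floral-unit counts and validate against `species`."""
    df = pd.read_csv(path)
    _check_columns(df, FLORAL_COLUMNS, path)
    df = df[FLORAL_COLUMNS].copy()
    df["date"] = _parse_dates(df, path)
    neg = df.index[df["floral_units"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative floral_units at row(s) {neg.tolist()}")
    key = ["site", "date", "plot_id", "species_id"]
    if df.duplicated(key).any():
        raise ValidationError(f"{path}: duplicate (site, date, plot_id, species_id) rows")
    _check_species_known(df, species, path)
    df["floral_units"] = df["floral_units"].astype(int)
    logger.info("read %d floral count records from %s", len(df), path)
    return df


def read_visits(path: str | Path, species: pd.DataFrame) -> pd.DataFrame:
    """Read per-plot insect visit counts (all recorded groups, unfiltered)."""
    df = pd.read_csv(path)
    _check_columns(df, VISIT_COLUMNS, path)
    df = df[VISIT_COLUMNS].copy()
    df["date"] = _parse_dates(df, path)
    bad = ~df["insect_group"].isin(INSECT_GROUPS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown insect_group {sorted(df.loc[bad, 'insect_group'].unique())}"
        )
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative count at row(s) {neg.tolist()}")
    _check_species_known(df, species, path)
    df["count"] = df["count"].astype(int)
    logger.info("read %d visit records from %s", len(df), path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the fixed CSV dialect (UTF-8, ISO dates, header)."""
    out = df.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def filter_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Keep only wild-pollinator visits (bees/wasps, hoverflies, butterflies).

    Honeybee records are dropped because *Apis mellifera* is a managed species;
    Coleoptera and Hemiptera are dropped as too scarce for analysis. Removal
    counts are logged per group. Idempotent.
    """
    keep = visits["insect_group"].isin(WILD_GROUPS)
    removed = visits.loc[~keep]
    if len(removed):
        for group, n in removed.groupby("insect_group", observed=True)["count"].sum().items():
            logger.info("filter_visits: removed %s rows totalling %d %s visits",
                        (removed["insect_group"] == group).sum(), n, group)
    return visits.loc[keep].reset_index(drop=True)


def visit_totals_by_group(visits: pd.DataFrame) -> pd.Series:
    """Total visit counts per insect group, plus a ``total`` entry."""
    totals = visits.groupby("insect_group", observed=True)["count"].sum()
    totals.loc["total"] = totals.sum()
    return totals


def assign_periods(
    dates: Iterable[dt.date] | pd.Series,
    boundaries: YearBoundaries | None = None,
) -> pd.DataFrame:
    """Map survey dates to (study_year, month_label).

    study_year is 1 on ``[year1_start, year2_start)`` and 2 on
    ``[year2_start, end)``; month_label is the calendar ``YYYY-MM`` of the
    occasion's date. Dates outside both intervals raise.
    """
    b = boundaries or YearBoundaries()
    s = pd.Series(pd.to_datetime(list(dates) if not isinstance(dates, pd.Series) else dates))
    d = s.dt.date
    out_of_range = (d < b.year1_start) | (d >= b.end)
    if out_of_range.any():
        bad = sorted({str(x) for x in d[out_of_range]})
        raise ValueError(f"date(s) outside the study window: {bad}")
    study_year = pd.Series(1, index=s.index)
    study_year[d >= b.year2_start] = 2
    return pd.DataFrame(
        {"date": d, "study_year": study_year, "month_label": s.dt.strftime("%Y-%m")}
    )


def validate_dataset(input_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read and cross-validate a full input directory.

    Expects ``species.csv``, ``floral_counts.csv`` and ``visits.csv``; the
    resource-measurement tables are validated by :mod:`florivis.resources`.
    Returns the validated tables keyed by name.
    """
    input_dir = Path(input_dir)
    species_path = input_dir / "species.csv"
    if not species_path.exists():
        raise FileNotFoundError(f"missing required file: {species_path}")
    species = read_species(species_path)
    tables: dict[str, pd.DataFrame] = {"species": species}
    for name, reader in [("floral_counts", read_floral_counts), ("visits", read_visits)]:
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing required file: {path}")
        tables[name] = reader(path, species)
    return tables
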