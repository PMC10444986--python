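"""Per-flower resource quantification: nectar sugar mass and pollen volume.

Nectar sugar mass per flower (µg) follows the refractometry relation

    s = 10 · d(C) · v · C

where ``v`` is the extracted nectar volume (µL), ``C`` the refractometer
reading (g sucrose per 100 g solution) and ``d`` the sucrose-solution
density (g/mL) given by the empirical polynomial

    d(C) = 0.0037921·C + 0.0000178·C² + 0.9988603 .

For flowers too small for direct capillary extraction, the nectaries are
rinsed with a fixed volume of distilled water (2 µL by default) and the same
relation is applied to the diluted reading, with the rinse volume in place
of ``v``.

Pollen per flower is counted from two 10-µL aliquots of a stamen suspension
of known volume ``U``; grains per flower N = mean(aliquots) · U / 10. Grain
volume is the ellipsoid V = 4/3·π·A·B² (µm³) from the semi-major and
semi-minor axes, and flower-level pollen volume is N·V converted to µL
(1 µL = 10⁹ µm³).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SchemaError, ValidationError, _check_columns

logger = logging.getLogger(__name__)

__all__ = [
    "sucrose_density",
    "nectar_sugar_mass",
    "grains_per_flower",
    "grain_volume",
    "pollen_volume_per_flower",
    "build_species_profiles",
    "measurement_coverage",
    "read_nectar_samples",
    "read_pollen_counts",
    "read_pollen_grains",
]

#: physical ceiling of sucrose refractometry, g sucrose / 100 g solution
MAX_CONCENTRATION = 85.0
#: µm³ per µL
UM3_PER_UL = 1e9

NECTAR_COLUMNS = [
    "species_id", "method", "nectar_volume_ul", "concentration", "rinse_volume_ul",
]
POLLEN_COUNT_COLUMNS = [
    "species_id", "sample_id", "aliquot_count_1", "aliquot_count_2", "suspension_volume_ul",
]
POLLEN_GRAIN_COLUMNS = ["species_id", "major_axis_um", "minor_axis_um"]


def sucrose_density(concentration, max_concentration: float = MAX_CONCENTRATION):
    """Density d (g/mL) of a sucrose solution at concentration C (g/100 g).

    Accepts scalars or arrays; strictly increasing on [0, max_concentration].
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or np.any(c > max_concentration):
        raise ValueError(
            f"concentration outside [0, {max_concentration}] g/100 g"
        )
    d = 0.0037921 * c + 0.0000178 * c**2 + 0.9988603
    return float(d) if np.isscalar(concentration) else d


def nectar_sugar_mass(
    method: str,
    concentration: float,
    nectar_volume_ul: float | None = None,
    rinse_volume_ul: float | None = None,
) -> float:
    """Sugar mass s (µg) in one flower's standing nectar, s = 10·d·v·C.

    ``direct``: v is the extracted nectar volume. ``rinse``: v is the rinse
    water volume and C the diluted-solution reading.
    """
    if method == "direct":
        if nectar_volume_ul is None or not np.isfinite(nectar_volume_ul):
            raise ValidationError("direct method requires nectar_volume_ul")
        v = float(nectar_volume_ul)
    elif method == "rinse":
        if rinse_volume_ul is None or not np.isfinite(rinse_volume_ul):
            raise ValidationError("rinse method requires rinse_volume_ul")
        v = float(rinse_volume_ul)
    else:
        raise ValidationError(f"unknown nectar method {method!r}")
    if v < 0:
        raise ValidationError("nectar volume must be >= 0")
    return 10.0 * sucrose_density(concentration) * v * float(concentration)


def grains_per_flower(
    aliquot_counts: tuple[float, float],
    suspension_volume_ul: float,
) -> float:
    """Total pollen grains per flower, N = mean(aliquots) · U / 10 µL."""
    a, b = aliquot_counts
    if a < 0 or b < 0:
        raise ValidationError("aliquot counts must be >= 0")
    if suspension_volume_ul <= 0:
        raise ValueError("suspension volume must be > 0")
    return (a + b) / 2.0 * suspension_volume_ul / 10.0


def grain_volume(major_axis_um: float, minor_axis_um: float) -> float:
    """Ellipsoid grain volume V = 4/3·π·A·B² (µm³), A/B = semi-axes."""
    if minor_axis_um <= 0 or major_axis_um <= 0:
        raise ValidationError("grain axes must be > 0")
    if minor_axis_um > major_axis_um:
        raise ValidationError("minor axis exceeds major axis")
    a = major_axis_um / 2.0
    b = minor_axis_um / 2.0
    return 4.0 / 3.0 * math.pi * a * b * b


def pollen_volume_per_flower(grains: float, grain_volume_um3: float) -> float:
    """Flower-level pollen volume (µL) = N · V / 10⁹."""
    if grains < 0 or grain_volume_um3 < 0:
        raise ValueError("grain count and volume must be >= 0")
    return grains * grain_volume_um3 / UM3_PER_UL


# ---------------------------------------------------------------------------
# measurement tables

def read_nectar_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, NECTAR_COLUMNS, path)
    df = df[NECTAR_COLUMNS].copy()
    bad = ~df["method"].isin({"direct", "rinse"})
    if bad.any():
        raise ValidationError(f"{path}: invalid nectar method at row(s) {df.index[bad].tolist()}")
    if (df["concentration"] < 0).any() or (df["concentration"] > MAX_CONCENTRATION).any():
        raise ValidationError(f"{path}: concentration outside [0, {MAX_CONCENTRATION}]")
    direct = df["method"] == "direct"
    if df.loc[direct, "nectar_volume_ul"].isna().any():
        raise ValidationError(f"{path}: direct rows missing nectar_volume_ul")
    if (df.loc[direct, "nectar_volume_ul"] < 0).any():
        raise ValidationError(f"{path}: negative nectar_volume_ul")
    if df.loc[~direct, "rinse_volume_ul"].isna().any():
        raise ValidationError(f"{path}: rinse rows missing rinse_volume_ul")
    return df


def read_pollen_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, POLLEN_COUNT_COLUMNS, path)
    df = df[POLLEN_COUNT_COLUMNS].copy()
    if (df[["aliquot_count_1", "aliquot_count_2"]] < 0).any().any():
        raise ValidationError(f"{path}: negative aliquot count")
    if (df["suspension_volume_ul"] <= 0).any():
        raise ValidationError(f"{path}: suspension volume must be > 0")
    return df


def read_pollen_grains(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, POLLEN_GRAIN_COLUMNS, path)
    df = df[POLLEN_GRAIN_COLUMNS].copy()
    if (df["minor_axis_um"] <= 0).any():
        raise ValidationError(f"{path}: grain axes must be > 0")
    if (df["minor_axis_um"] > df["major_axis_um"]).any():
        raise ValidationError(f"{path}: minor axis exceeds major axis")
    return df


# ---------------------------------------------------------------------------
# species profiles

def build_species_profiles(
    nectar: pd.DataFrame | None,
    pollen_counts: pd.DataFrame | None,
    pollen_grains: pd.DataFrame | None,
    species: pd.DataFrame,
) -> pd.DataFrame:
    """Per-species mean resource profiles.

    Returns one row per species in `species` with columns ``mean_sugar_ug``,
    ``mean_pollen_ul``, ``n_nectar``, ``n_pollen``. Unmeasured resources are
    NaN with a zero sample count — absence of measurement is never coded as
    a zero resource value.

    Pollen per flower multiplies the species-mean grain count by the grain
    volume computed from the species-mean axis lengths (means are taken
    before multiplication). A species needs both count and grain-size
    samples for a pollen value; ``n_pollen`` is the number of count samples.
    """
    prof = species[["species_id"]].copy()

    if nectar is not None and len(nectar):
        s = nectar.apply(
            lambda r: nectar_sugar_mass(
                r["method"], r["concentration"],
                r.get("nectar_volume_ul"), r.get("rinse_volume_ul"),
            ),
            axis=1,
        )
        agg = pd.DataFrame({"species_id": nectar["species_id"], "s": s}).groupby(
            "species_id"
        )["s"].agg(["mean", "size"])
        prof = prof.merge(
            agg.rename(columns={"mean": "mean_sugar_ug", "size": "n_nectar"}),
            left_on="species_id", right_index=True, how="left",
        )
    else:
        prof["mean_sugar_ug"] = np.nan
        prof["n_nectar"] = 0

    mean_grains = None
    if pollen_counts is not None and len(pollen_counts):
        n = pollen_counts.apply(
            lambda r: grains_per_flower(
                (r["aliquot_count_1"], r["aliquot_count_2"]),
                r["suspension_volume_ul"],
            ),
            axis=1,
        )
        mean_grains = pd.DataFrame(
            {"species_id": pollen_counts["species_id"], "n": n}
        ).groupby("species_id")["n"].agg(["mean", "size"])

    mean_vol = None
    if pollen_grains is not None and len(pollen_grains):
        axes = pollen_grains.groupby("species_id")[
            ["major_axis_um", "minor_axis_um"]
        ].mean()
        mean_vol = axes.apply(
            lambda r: grain_volume(r["major_axis_um"], r["minor_axis_um"]), axis=1
        )

    if mean_grains is not None and mean_vol is not None:
        joined = mean_grains.join(mean_vol.rename("v_um3"), how="inner")
        pollen_ul = joined.apply(
            lambda r: pollen_volume_per_flower(r["mean"], r["v_um3"]), axis=1
        )
        prof = prof.merge(
            pd.DataFrame({"mean_pollen_ul": pollen_ul, "n_pollen": joined["size"]}),
            left_on="species_id", right_index=True, how="left",
        )
    else:
        prof["mean_pollen_ul"] = np.nan
        prof["n_pollen"] = 0

    prof["n_nectar"] = prof["n_nectar"].fillna(0).astype(int)
    prof["n_pollen"] = prof["n_pollen"].fillna(0).astype(int)
    logger.info(
        "profiles: %d species, %d nectar-measured, %d pollen-measured",
        len(prof), (prof["n_nectar"] > 0).sum(), (prof["n_pollen"] > 0).sum(),
    )
    return prof


def measurement_coverage(profiles: pd.DataFrame, species: pd.DataFrame) -> dict[str, float]:
    """Percent of species with measured resources.

    Nectar coverage is relative to species *with nectaries* (nectarless
    species cannot be nectar-measured); pollen coverage is relative to all
    species. Percentages are rounded to one decimal, as conventionally
    reported.
    """
    merged = profiles.merge(species, on="species_id")
    with_nectaries = merged[merged["has_nectaries"]]
    nectar_pct = (
        100.0 * (with_nectaries["n_nectar"] > 0).sum() / len(with_nectaries)
        if len(with_nectaries) else float("nan")
    )
    pollen_pct = 100.0 * (merged["n_pollen"] > 0).sum() / len(merged)
    return {
        "nectar_species_pct": round(float(nectar_pct), 1),
        "pollen_species_pct": round(float(pollen_pct), 1),
        "n_species_with_nectaries": int(len(with_nectaries)),
        "n_nectar_measured": int((with_nectaries["n_nectar"] > 0).sum()),
        "n_species": int(len(merged)),
        "n_pollen_measured": int((merged["n_pollen"] > 0).sum()),
    }
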