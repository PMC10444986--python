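"""Seed-deterministic synthetic survey datasets.

The generator emulates the structure of a two-year riparian flowering /
visitation survey: four river sites, five 1 m² plots per site, survey
occasions every two weeks in the first study year and monthly in the
second, and a community of ~30 co-flowering species. Four alien archetypes
flower for ~200 days with high per-flower nectar sugar and pollen (the
roles of *Erigeron annuus*, *Trifolium pratense*, *Bidens pilosa* and
*Solidago altissima* in the real communities), against ~26 shorter-
flowering, resource-poorer natives whose peaks are spread over the season —
which makes community-level resource availability bimodal (late
spring/early summer and autumn) and dominated by the aliens.

Floral counts are negative-binomial draws around a Gaussian-in-time
phenology curve, zero outside each species' flowering window. Raw nectar
and pollen field measurements are emitted such that the quantification
pipeline recovers each species' true per-flower means. Insect visits are
drawn per plot and occasion from group-level seasonal activity curves and
allocated to co-flowering species under one of three regimes:

``resource_proportional``
    visit weights follow each species' share of combined (unit-normalized
    sugar + pollen) availability in the plot — the "resource-rich plants
    are visited most" hypothesis;
``even_preference``
    weights follow configured preference weights among whatever is
    flowering, independent of resource content — the "visited like any
    other flowering plant" hypothesis;
``native_biased``
    even preference with native weights inflated by a configurable factor.

Honeybee, Coleoptera and Hemiptera rows are also emitted (small numbers)
so the wild-pollinator filter is exercised end to end.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import WILD_GROUPS, YearBoundaries, write_table
from .resources import sucrose_density

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesArchetype",
    "GroupActivity",
    "SimulationConfig",
    "SyntheticDataset",
    "default_archetypes",
    "default_group_activities",
    "survey_dates",
    "simulate_phenology_counts",
    "simulate_resource_samples",
    "simulate_visits",
    "generate",
    "expected_resource_curve",
]

REGIMES = ("resource_proportional", "even_preference", "native_biased")
NONWILD_GROUPS = ("honeybee", "coleoptera", "hemiptera")


@dataclass(frozen=True)
class SpeciesArchetype:
    """Generating parameters for one synthetic species.

    ``peak_day`` counts days from the start of each study year; phenology
    repeats in both years. ``sugar_mean_ug`` / ``pollen_mean_ul`` are the
    true per-flower means; ``None`` marks a resource as unmeasured (no
    measurement rows are emitted, but the species still produces the
    resource when visits are allocated resource-proportionally).
    """

    species_id: str
    origin: str  # alien | native
    peak_day: float
    duration_days: float
    peak_units: float  # expected open floral units per plot at peak
    sugar_mean_ug: float | None
    pollen_mean_ul: float | None
    has_nectaries: bool = True
    floral_unit_type: str = "flower"
    sugar_sigma_log: float = 0.5  # lognormal sigma of per-flower sugar
    pollen_sigma_log: float = 0.5
    grain_major_um: float = 30.0
    grain_minor_um: float = 24.0
    preference_weight: float = 1.0


@dataclass(frozen=True)
class GroupActivity:
    """Seasonal activity of one insect group: a sum of Gaussian pulses
    (peak_day, sd_days, weight) over the study-year cycle."""

    group: str
    pulses: tuple[tuple[float, float, float], ...]

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for peak, sd, w in self.pulses:
            out = out + w * np.exp(-0.5 * ((t - peak) / sd) ** 2)
        return out


def default_archetypes() -> tuple[SpeciesArchetype, ...]:
    """The default 30-species community: 4 resource-rich long-flowering
    aliens and 26 natives with staggered, shorter phenologies."""
    aliens = [
        SpeciesArchetype("alien_daisy", "alien", 55.0, 200.0, 120.0,
                         1200.0, 0.8, floral_unit_type="head"),
        SpeciesArchetype("alien_clover", "alien", 65.0, 200.0, 60.0,
                         2500.0, 1.2, floral_unit_type="head"),
        SpeciesArchetype("alien_beggartick", "alien", 170.0, 200.0, 80.0,
                         900.0, 0.6, floral_unit_type="head"),
        SpeciesArchetype("alien_goldenrod", "alien", 185.0, 200.0, 100.0,
                         700.0, 0.5, floral_unit_type="head"),
    ]
    natives = []
    # nectar unmeasured for three natives, one nectarless species, pollen
    # unmeasured for three others; two very-small-flowered species use the
    # rinse method downstream (tiny sugar mass)
    for i in range(26):
        sugar: float | None = 20.0 + (i % 7) * 25.0
        nectaries = True
        if i in (3, 11, 19):
            sugar = None
        if i == 7:
            sugar, nectaries = None, False
        if i == 0:
            sugar = 8.0
        if i == 14:
            sugar = 12.0
        pollen: float | None = 0.02 + (i % 5) * 0.02
        if i in (5, 13, 21):
            pollen = None
        natives.append(
            SpeciesArchetype(
                f"native_{i:02d}", "native",
                peak_day=15.0 + i * 8.5,
                duration_days=50.0,
                peak_units=10.0 + (i % 5) * 10.0,
                sugar_mean_ug=sugar,
                pollen_mean_ul=pollen,
                has_nectaries=nectaries,
                grain_major_um=20.0 + (i % 6) * 4.0,
                grain_minor_um=16.0 + (i % 6) * 3.0,
            )
        )
    return tuple(aliens + natives)


def default_group_activities() -> tuple[GroupActivity, ...]:
    """Wild-group activity curves tracking the bimodal floral season:
    bees/wasps peak in late spring and autumn, hoverflies are broad,
    butterflies peak in late summer–autumn."""
    return (
        GroupActivity("bee_wasp", ((55.0, 30.0, 1.0), (180.0, 30.0, 0.7))),
        GroupActivity("hoverfly", ((80.0, 60.0, 1.0), (190.0, 40.0, 0.6))),
        GroupActivity("butterfly", ((150.0, 50.0, 1.0),)),
    )


@dataclass
class SimulationConfig:
    """Full generating configuration; the seed fixes every draw."""

    seed: int = 0
    sites: tuple[str, ...] = ("site1", "site2", "site3", "site4")
    n_plots: int = 5
    boundaries: YearBoundaries = field(default_factory=YearBoundaries)
    year1_interval_days: int = 14
    year2_interval_days: int = 30
    archetypes: tuple[SpeciesArchetype, ...] = field(default_factory=default_archetypes)
    group_activities: tuple[GroupActivity, ...] = field(default_factory=default_group_activities)
    regime: str = "even_preference"
    visits_per_site_year: float = 10_000.0
    theta_counts: float = 2.0
    theta_visits: float = 2.0
    native_bias: float = 3.0
    nonwild_rate: float = 0.2  # mean non-wild visits per plot-occasion per group
    n_nectar_range: tuple[int, int] = (5, 53)
    n_pollen_range: tuple[int, int] = (5, 27)
    n_grain_range: tuple[int, int] = (8, 60)
    rinse_sugar_threshold_ug: float = 15.0  # below this, nectar sampled by rinsing

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        ids = [a.species_id for a in self.archetypes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species_id in archetypes")


@dataclass
class SyntheticDataset:
    """Generated input tables plus the ground truth that produced them."""

    species: pd.DataFrame
    floral_counts: pd.DataFrame
    visits: pd.DataFrame
    nectar_samples: pd.DataFrame
    pollen_counts: pd.DataFrame
    pollen_grains: pd.DataFrame
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("species", "floral_counts", "visits", "nectar_samples",
                     "pollen_counts", "pollen_grains"):
            write_table(getattr(self, name), out / f"{name}.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# survey calendar

def survey_dates(config: SimulationConfig) -> list[dt.date]:
    """Survey occasions: fixed cadence within each study year."""
    b = config.boundaries
    dates = []
    d = b.year1_start
    while d < b.year2_start:
        dates.append(d)
        d += dt.timedelta(days=config.year1_interval_days)
    d = b.year2_start
    while d < b.end:
        dates.append(d)
        d += dt.timedelta(days=config.year2_interval_days)
    return dates


def _cycle_day(date: dt.date, b: YearBoundaries) -> float:
    """Days since the start of the date's study year."""
    start = b.year1_start if date < b.year2_start else b.year2_start
    return float((date - start).days)


def _phenology_mean(arch: SpeciesArchetype, t: float) -> float:
    """Expected open floral units per plot at cycle day t; zero outside the
    flowering window peak ± duration/2."""
    if abs(t - arch.peak_day) > arch.duration_days / 2.0:
        return 0.0
    sd = arch.duration_days / 6.0
    return arch.peak_units * float(np.exp(-0.5 * ((t - arch.peak_day) / sd) ** 2))


def _nbinom_draw(rng: np.random.Generator, mean, theta: float):
    """Negative binomial with mean `mean` and dispersion theta."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


# ---------------------------------------------------------------------------
# stage generators

def simulate_phenology_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Floral-count table: NB draws around each species' phenology curve.

    Only nonzero counts are emitted (absent rows mean no open units, as in
    the survey convention).
    """
    rng = rng or np.random.default_rng(config.seed)
    dates = survey_dates(config)
    rows = []
    for site in config.sites:
        for date in dates:
            t = _cycle_day(date, config.boundaries)
            for arch in config.archetypes:
                mu = _phenology_mean(arch, t)
                if mu <= 0:
                    continue
                counts = _nbinom_draw(
                    rng, np.full(config.n_plots, mu), config.theta_counts
                )
                for p, c in enumerate(counts, start=1):
                    if c > 0:
                        rows.append((site, date, f"plot{p}", arch.species_id, int(c)))
    df = pd.DataFrame(
        rows, columns=["site", "date", "plot_id", "species_id", "floral_units"]
    )
    logger.info("simulated %d floral count rows", len(df))
    return df


def _solve_rinse_concentration(s_ug: float, rinse_ul: float) -> float:
    """Diluted-reading concentration C with 10·d(C)·rinse·C = s."""
    if s_ug <= 0:
        return 0.0
    f = lambda c: 10.0 * sucrose_density(c) * rinse_ul * c - s_ug
    return brentq(f, 0.0, 85.0)


def simulate_resource_samples(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Raw nectar and pollen measurement tables.

    Per-sample per-flower sugar masses are lognormal around each species'
    true mean and re-expressed as (volume, concentration) readings; pollen
    is expressed as aliquot counts over a suspension volume plus grain-axis
    measurements, so that the quantification pipeline recovers the true
    means. Zero-variance archetypes round-trip exactly.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    nectar_rows, count_rows, grain_rows = [], [], []
    for arch in config.archetypes:
        if arch.sugar_mean_ug is not None:
            n = int(rng.integers(*config.n_nectar_range, endpoint=True))
            sigma = arch.sugar_sigma_log
            if sigma > 0:
                mu_log = np.log(arch.sugar_mean_ug) - sigma**2 / 2.0
                masses = rng.lognormal(mu_log, sigma, size=n)
            else:
                masses = np.full(n, arch.sugar_mean_ug)
            use_rinse = arch.sugar_mean_ug < config.rinse_sugar_threshold_ug
            conc = float(rng.uniform(20.0, 50.0))
            for s in masses:
                if use_rinse:
                    c = _solve_rinse_concentration(float(s), 2.0)
                    nectar_rows.append(
                        (arch.species_id, "rinse", np.nan, c, 2.0)
                    )
                else:
                    v = float(s) / (10.0 * sucrose_density(conc) * conc)
                    nectar_rows.append(
                        (arch.species_id, "direct", v, conc, np.nan)
                    )
        if arch.pollen_mean_ul is not None:
            v_grain = (4.0 / 3.0) * np.pi * (arch.grain_major_um / 2.0) * (
                arch.grain_minor_um / 2.0
            ) ** 2
            n_true = arch.pollen_mean_ul * 1e9 / v_grain  # grains per flower
            n = int(rng.integers(*config.n_pollen_range, endpoint=True))
            sigma = arch.pollen_sigma_log
            if sigma > 0:
                mu_log = np.log(n_true) - sigma**2 / 2.0
                grains = rng.lognormal(mu_log, sigma, size=n)
            else:
                grains = np.full(n, n_true)
            for i, g in enumerate(grains):
                # pick an aliquot count near 50 grains/10 µL, then set the
                # suspension volume so mean(counts)·U/10 returns g exactly
                u0 = max(30.0, min(1000.0, g * 10.0 / 50.0))
                c = max(1, int(round(g * 10.0 / u0)))
                u = 10.0 * g / c
                count_rows.append((arch.species_id, f"{arch.species_id}_s{i}", c, c, u))
            n_grains = int(rng.integers(*config.n_grain_range, endpoint=True))
            if sigma > 0:
                major = arch.grain_major_um * rng.lognormal(-0.05**2 / 2, 0.05, n_grains)
                ratio = arch.grain_minor_um / arch.grain_major_um
                minor = np.minimum(major * ratio * rng.lognormal(-0.02**2 / 2, 0.02, n_grains), major)
            else:
                major = np.full(n_grains, arch.grain_major_um)
                minor = np.full(n_grains, arch.grain_minor_um)
            for ma, mi in zip(major, minor):
                grain_rows.append((arch.species_id, float(ma), float(mi)))
    nectar = pd.DataFrame(
        nectar_rows,
        columns=["species_id", "method", "nectar_volume_ul", "concentration", "rinse_volume_ul"],
    )
    counts = pd.DataFrame(
        count_rows,
        columns=["species_id", "sample_id", "aliquot_count_1", "aliquot_count_2", "suspension_volume_ul"],
    )
    grains = pd.DataFrame(
        grain_rows, columns=["species_id", "major_axis_um", "minor_axis_um"]
    )
    return nectar, counts, grains


def _regime_weights(
    config: SimulationConfig,
    archs: list[SpeciesArchetype],
    units: np.ndarray,
    sugar_norm: np.ndarray,
    pollen_norm: np.ndarray,
) -> np.ndarray:
    if config.regime == "resource_proportional":
        return units * (sugar_norm + pollen_norm)
    w = np.array([a.preference_weight for a in archs], dtype=float)
    if config.regime == "native_biased":
        w = w * np.array(
            [config.native_bias if a.origin == "native" else 1.0 for a in archs]
        )
    return w * (units > 0)


def simulate_visits(
    config: SimulationConfig,
    floral_counts: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Visit table: NB group totals per plot/occasion allocated to the
    plot's flowering species by the configured regime.

    Group totals follow the group's seasonal activity curve, normalized so
    that the expected number of wild visits per site and study year equals
    ``visits_per_site_year``. Non-wild rows (honeybee, Coleoptera,
    Hemiptera) are added at a low rate.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    b = config.boundaries
    dates = survey_dates(config)
    archs = list(config.archetypes)
    arch_index = {a.species_id: i for i, a in enumerate(archs)}

    # unit-free combined resource index per species (relative to community means)
    sugar = np.array([a.sugar_mean_ug or 0.0 for a in archs])
    pollen = np.array([a.pollen_mean_ul or 0.0 for a in archs])
    sugar_norm = sugar / sugar[sugar > 0].mean()
    pollen_norm = pollen / pollen[pollen > 0].mean()

    # per-year normalization of the activity curves
    year_of = {d: (1 if d < b.year2_start else 2) for d in dates}
    scale = {}
    for year in (1, 2):
        ts = np.array([_cycle_day(d, b) for d in dates if year_of[d] == year])
        total_activity = sum(
            ga.value(ts).sum() for ga in config.group_activities
        ) * config.n_plots
        scale[year] = config.visits_per_site_year / total_activity

    counts_idx: dict[tuple, np.ndarray] = {}
    units_by_key: dict[tuple, np.ndarray] = {}
    for (site, date, plot), grp in floral_counts.groupby(
        ["site", "date", "plot_id"], observed=True
    ):
        units = np.zeros(len(archs))
        units[[arch_index[s] for s in grp["species_id"]]] = grp["floral_units"].to_numpy()
        units_by_key[(site, date, plot)] = units

    rows = []
    plot_ids = [f"plot{p}" for p in range(1, config.n_plots + 1)]
    for site in config.sites:
        for date in dates:
            t = _cycle_day(date, b)
            for plot in plot_ids:
                units = units_by_key.get((site, date, plot))
                if units is None or units.sum() == 0:
                    continue
                weights = _regime_weights(config, archs, units, sugar_norm, pollen_norm)
                flowering = units > 0
                weights = weights * flowering
                if weights.sum() <= 0:
                    continue
                probs = weights / weights.sum()
                for ga in config.group_activities:
                    mu = scale[year_of[date]] * float(ga.value(np.array([t]))[0])
                    total = int(_nbinom_draw(rng, np.array([mu]), config.theta_visits)[0])
                    if total == 0:
                        continue
                    alloc = rng.multinomial(total, probs)
                    for i in np.nonzero(alloc)[0]:
                        rows.append(
                            (site, date, plot, archs[i].species_id, ga.group, int(alloc[i]))
                        )
                # sparse non-wild visitors on a random flowering species
                for group in NONWILD_GROUPS:
                    c = int(rng.poisson(config.nonwild_rate))
                    if c > 0:
                        i = int(rng.choice(np.nonzero(flowering)[0]))
                        rows.append((site, date, plot, archs[i].species_id, group, c))
    df = pd.DataFrame(
        rows, columns=["site", "date", "plot_id", "species_id", "insect_group", "count"]
    )
    logger.info("simulated %d visit rows (%d wild visits)",
                len(df), df.loc[df["insect_group"].isin(WILD_GROUPS), "count"].sum())
    return df


def generate(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full synthetic dataset (tables + ground truth).

    Deterministic in ``config.seed``: the same seed yields byte-identical
    tables. If `out_dir` is given the CSVs and ``ground_truth.json`` are
    written there.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    species = pd.DataFrame(
        {
            "species_id": [a.species_id for a in config.archetypes],
            "origin": [a.origin for a in config.archetypes],
            "has_nectaries": [a.has_nectaries for a in config.archetypes],
            "floral_unit_type": [a.floral_unit_type for a in config.archetypes],
        }
    )
    floral_counts = simulate_phenology_counts(config, rng)
    nectar, pollen_counts, pollen_grains = simulate_resource_samples(config, rng)
    visits = simulate_visits(config, floral_counts, rng)
    ground_truth = {
        "seed": config.seed,
        "regime": config.regime,
        "visits_per_site_year": config.visits_per_site_year,
        "species": {
            a.species_id: {
                "origin": a.origin,
                "peak_day": a.peak_day,
                "duration_days": a.duration_days,
                "peak_units": a.peak_units,
                "sugar_mean_ug": a.sugar_mean_ug,
                "pollen_mean_ul": a.pollen_mean_ul,
                "preference_weight": a.preference_weight,
            }
            for a in config.archetypes
        },
        "group_activity_peaks": {
            ga.group: [p for p, _, _ in ga.pulses] for ga in config.group_activities
        },
    }
    ds = SyntheticDataset(
        species=species,
        floral_counts=floral_counts,
        visits=visits,
        nectar_samples=nectar,
        pollen_counts=pollen_counts,
        pollen_grains=pollen_grains,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def expected_resource_curve(
    config: SimulationConfig, resource: str = "sugar", t_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """True expected community availability per plot over the year cycle.

    Useful as ground truth for peak-recovery checks: columns ``t`` (cycle
    day) and ``value`` (µg/m² for sugar, µL/m² for pollen).
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 365.0)
    attr = {"sugar": "sugar_mean_ug", "pollen": "pollen_mean_ul"}[resource]
    values = np.zeros_like(t_grid, dtype=float)
    for arch in config.archetypes:
        mean = getattr(arch, attr)
        if mean is None:
            continue
        values += np.array([_phenology_mean(arch, t) for t in t_grid]) * mean
    return pd.DataFrame({"t": t_grid, "value": values})
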