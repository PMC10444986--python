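"""Seasonal GAM trends of resource availability and insect visits.

Each series is one response at one site: the plot × occasion observations
over census day (days since the site's first survey), spanning both study
years. Resource series (sugar µg/m², pollen µL/m²) are shifted by +0.0001
and fitted with a gamma family and log link, so that zero plot totals are
admissible in a positive continuous model. Visit counts are fitted with a
negative-binomial family (log link) whose theta is estimated during
fitting. The smooth is a penalized spline of census day with basis
dimension k = 10; smoothing parameters are chosen by GCV for gamma models
and REML for negative-binomial models (theta estimation requires an
ML-type criterion). Fitting is delegated to mgcv, batched over series in a
single R session.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import WILD_GROUPS, filter_visits

logger = logging.getLogger(__name__)

__all__ = [
    "GAM_OFFSET",
    "SeasonalTrendFit",
    "TrendSeries",
    "fit_gam_batch",
    "fit_resource_trend",
    "fit_visit_trend",
    "fit_site_trends",
    "trend_summary_table",
    "prediction_table",
    "detect_peaks",
]

#: additive offset applied to resource responses before the gamma fit
GAM_OFFSET = 1e-4
RESOURCE_RESPONSES = ("sugar", "pollen")
VISIT_RESPONSES = ("visits_all",) + tuple(f"visits_{g}" for g in WILD_GROUPS)


@dataclass
class TrendSeries:
    """One fitting unit: response values over census day."""

    series_id: str
    day: np.ndarray
    y: np.ndarray
    site: str = ""
    response: str = ""


@dataclass
class SeasonalTrendFit:
    """Summary of one fitted seasonal GAM."""

    site: str
    response: str
    family: str  # gamma_log | negbin_log
    n_obs: int
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    edf: float = float("nan")
    ref_df: float = float("nan")
    statistic: float = float("nan")
    p_value: float = float("nan")
    deviance_explained: float = float("nan")  # percent
    theta: float | None = None
    curve: pd.DataFrame | None = None  # census_day, prediction
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def significant(self, alpha: float = 0.05) -> bool:
        """Whether the smooth term detects seasonality at level `alpha`."""
        return self.ok and self.p_value < alpha


def _rscript_path() -> Path:
    return Path(str(importlib_resources.files("florivis") / "_gam.R"))


def fit_gam_batch(
    series: list[TrendSeries],
    family: str,
    k: int = 10,
    n_pred: int = 200,
    method: str | None = None,
) -> list[SeasonalTrendFit]:
    """Fit ``y ~ s(day, k)`` for every series in one R (mgcv) session.

    `family` is ``"gamma"`` or ``"negbin"``. A per-series fitting failure
    yields a flagged :class:`SeasonalTrendFit` (``.error`` set), not an
    exception.
    """
    if family not in {"gamma", "negbin"}:
        raise ValueError("family must be 'gamma' or 'negbin'")
    if method is None:
        method = "GCV.Cp" if family == "gamma" else "REML"
    fam_label = "gamma_log" if family == "gamma" else "negbin_log"
    degenerate: dict[str, SeasonalTrendFit] = {}
    to_fit = []
    for s in series:
        if len(np.unique(s.day)) < 3:
            raise ValueError(
                f"series {s.series_id}: need >= 3 distinct census days"
            )
        if np.ptp(s.y) == 0:
            # constant response: the intercept-only limit. A spline fit is
            # meaningless here (zero residual variance), so report a flat
            # curve with no evidence of seasonality.
            grid = np.linspace(s.day.min(), s.day.max(), n_pred)
            const = float(s.y[0])
            degenerate[s.series_id] = SeasonalTrendFit(
                site=s.site, response=s.response, family=fam_label,
                n_obs=len(s.y),
                intercept=float(np.log(const)) if const > 0 else float("-inf"),
                intercept_se=0.0, edf=0.0, ref_df=0.0, statistic=0.0,
                p_value=1.0, deviance_explained=0.0,
                curve=pd.DataFrame(
                    {"census_day": grid, "prediction": np.full(n_pred, const)}
                ),
            )
        else:
            to_fit.append(s)
    if not to_fit:
        return [degenerate[s.series_id] for s in series]
    frames = [
        pd.DataFrame({"series_id": s.series_id, "day": s.day, "y": s.y})
        for s in to_fit
    ]
    with tempfile.TemporaryDirectory(prefix="florivis_gam_") as tmp:
        tmp = Path(tmp)
        in_csv, sum_csv, pred_csv = tmp / "in.csv", tmp / "sum.csv", tmp / "pred.csv"
        pd.concat(frames, ignore_index=True).to_csv(in_csv, index=False)
        cmd = [
            "Rscript", "--vanilla", str(_rscript_path()),
            str(in_csv), str(sum_csv), str(pred_csv),
            family, str(k), str(n_pred), method,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"mgcv backend failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        summary = pd.read_csv(sum_csv).set_index("series_id")
        preds = pd.read_csv(pred_csv)
    fits = []
    for s in series:
        if s.series_id in degenerate:
            fits.append(degenerate[s.series_id])
            continue
        row = summary.loc[s.series_id]
        err = row["error"] if isinstance(row["error"], str) and row["error"] else None
        curve = None
        if err is None:
            sub = preds[preds["series_id"] == s.series_id]
            curve = pd.DataFrame(
                {"census_day": sub["day"].to_numpy(),
                 "prediction": sub["prediction"].to_numpy()}
            )
        fits.append(
            SeasonalTrendFit(
                site=s.site, response=s.response, family=fam_label,
                n_obs=int(row["n_obs"]),
                intercept=float(row["intercept"]),
                intercept_se=float(row["intercept_se"]),
                edf=float(row["edf"]), ref_df=float(row["ref_df"]),
                statistic=float(row["statistic"]), p_value=float(row["p_value"]),
                deviance_explained=float(row["dev_expl_pct"]),
                theta=(float(row["theta"]) if np.isfinite(row["theta"]) else None),
                curve=curve, error=err,
            )
        )
        if err:
            logger.warning("fit %s/%s failed: %s", s.site, s.response, err)
    return fits


def _census_days(dates: pd.Series, origin=None) -> np.ndarray:
    d = pd.to_datetime(dates)
    if origin is None:
        origin = d.min()
    return (d - pd.to_datetime(origin)).dt.days.to_numpy()


def fit_resource_trend(
    totals: pd.DataFrame,
    site: str,
    resource: str,
    k: int = 10,
    n_pred: int = 200,
    method: str = "GCV.Cp",
) -> SeasonalTrendFit:
    """Gamma log-link GAM of one site's plot-level resource totals.

    `totals` is the per-plot/occasion table from
    :func:`florivis.availability.plot_availability`; `resource` is
    ``"sugar"`` or ``"pollen"``. The response is value + 0.0001.
    """
    col = {"sugar": "sugar_ug_m2", "pollen": "pollen_ul_m2"}[resource]
    sub = totals[totals["site"] == site]
    if len(sub) < 20:
        raise ValueError(f"{site}/{resource}: need >= 20 observations, got {len(sub)}")
    series = TrendSeries(
        series_id=f"{site}:{resource}",
        day=_census_days(sub["date"]),
        y=sub[col].to_numpy(dtype=float) + GAM_OFFSET,
        site=site, response=resource,
    )
    return fit_gam_batch([series], "gamma", k=k, n_pred=n_pred, method=method)[0]


def _visit_series(visits: pd.DataFrame, site: str, group: str | None) -> pd.DataFrame:
    """Plot x occasion wild-visit counts for one site, one group or pooled."""
    wild = filter_visits(visits)
    sub = wild[wild["site"] == site]
    if group is not None:
        sub = sub[sub["insect_group"] == group]
    return (
        sub.groupby(["date", "plot_id"], observed=True)["count"].sum().reset_index()
    )


def fit_visit_trend(
    visits: pd.DataFrame,
    site: str,
    group: str | None = None,
    k: int = 10,
    n_pred: int = 200,
    method: str = "REML",
) -> SeasonalTrendFit:
    """Negative-binomial log-link GAM of plot-level visit counts.

    `group` is one of the wild groups, or None for the pooled response.
    All-zero or empty count series yield a flagged (not raised) fit.
    """
    response = f"visits_{group}" if group else "visits_all"
    agg = _visit_series(visits, site, group)
    if len(agg) == 0 or agg["count"].sum() == 0:
        return SeasonalTrendFit(
            site=site, response=response, family="negbin_log",
            n_obs=len(agg), error="no nonzero counts to fit",
        )
    series = TrendSeries(
        series_id=f"{site}:{response}",
        day=_census_days(agg["date"]),
        y=agg["count"].to_numpy(dtype=float),
        site=site, response=response,
    )
    return fit_gam_batch([series], "negbin", k=k, n_pred=n_pred, method=method)[0]


def fit_site_trends(
    totals: pd.DataFrame,
    visits: pd.DataFrame,
    sites: list[str] | None = None,
    k: int = 10,
    n_pred: int = 200,
) -> list[SeasonalTrendFit]:
    """All six responses (2 resources + 4 visit series) for each site.

    Batches the gamma and negbin fits into two R sessions.
    """
    if sites is None:
        sites = sorted(set(totals["site"]) | set(visits["site"]))
    gamma_series, negbin_series, flagged = [], [], []
    for site in sites:
        sub = totals[totals["site"] == site]
        for resource, col in [("sugar", "sugar_ug_m2"), ("pollen", "pollen_ul_m2")]:
            gamma_series.append(
                TrendSeries(
                    series_id=f"{site}:{resource}",
                    day=_census_days(sub["date"]),
                    y=sub[col].to_numpy(dtype=float) + GAM_OFFSET,
                    site=site, response=resource,
                )
            )
        for group in (None,) + tuple(WILD_GROUPS):
            response = f"visits_{group}" if group else "visits_all"
            agg = _visit_series(visits, site, group)
            if len(agg) == 0 or agg["count"].sum() == 0:
                flagged.append(
                    SeasonalTrendFit(
                        site=site, response=response, family="negbin_log",
                        n_obs=len(agg), error="no nonzero counts to fit",
                    )
                )
                continue
            negbin_series.append(
                TrendSeries(
                    series_id=f"{site}:{response}",
                    day=_census_days(agg["date"]),
                    y=agg["count"].to_numpy(dtype=float),
                    site=site, response=response,
                )
            )
    fits = []
    if gamma_series:
        fits += fit_gam_batch(gamma_series, "gamma", k=k, n_pred=n_pred)
    if negbin_series:
        fits += fit_gam_batch(negbin_series, "negbin", k=k, n_pred=n_pred)
    return fits + flagged


def trend_summary_table(fits: list[SeasonalTrendFit]) -> pd.DataFrame:
    """Flat summary (one row per fit) for trends.csv."""
    return pd.DataFrame(
        [
            {
                "site": f.site, "response": f.response, "family": f.family,
                "n_obs": f.n_obs, "intercept": f.intercept,
                "intercept_se": f.intercept_se, "edf": f.edf,
                "ref_df": f.ref_df, "statistic": f.statistic,
                "p_value": f.p_value, "deviance_explained": f.deviance_explained,
                "theta": f.theta if f.theta is not None else float("nan"),
                "error": f.error or "",
            }
            for f in fits
        ]
    )


def prediction_table(fits: list[SeasonalTrendFit]) -> pd.DataFrame:
    """Long fitted-curve table (site, response, census_day, prediction)."""
    frames = []
    for f in fits:
        if f.curve is not None:
            c = f.curve.copy()
            c.insert(0, "response", f.response)
            c.insert(0, "site", f.site)
            frames.append(c)
    if not frames:
        return pd.DataFrame(columns=["site", "response", "census_day", "prediction"])
    return pd.concat(frames, ignore_index=True)


def detect_peaks(
    curve: pd.DataFrame, rel_prominence: float = 0.1
) -> np.ndarray:
    """Census days of local maxima of a fitted curve.

    A maximum must be prominent by at least `rel_prominence` of the curve's
    range, which suppresses numerical ripple on near-flat fits.
    """
    y = curve["prediction"].to_numpy()
    rng = y.max() - y.min()
    if rng <= 0:
        return np.array([])
    idx, _ = find_peaks(y, prominence=rel_prominence * rng)
    return curve["census_day"].to_numpy()[idx]
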