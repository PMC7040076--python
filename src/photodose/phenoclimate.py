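"""Thermal-season segmentation and weather covariates.

Seasons are defined thermally from daily mean air temperature: spring
starts when it is continuously above 0 °C, summer above +10 °C, autumn
when it falls continuously below +10 °C, and winter below 0 °C.
"Continuously" is operationalised as a run of at least ``N`` consecutive
days (default 5) meeting the threshold; each season is searched for
strictly after the previous assigned season's start.

From the segmentation and a snow-depth series the module derives the
covariates related to leaf flavonol trends: days post snowmelt, days
prior to the first marked snowfall, days from the start of the thermal
growing season, and the effective temperature sum (degree-days above a
base temperature, default +5 °C as in Fennoscandian practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ("doy", "t_mean", "t_min", "t_max", "snow_depth_cm")



def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, daily contiguity and t_min ≤ t_mean ≤ t_max."""
    missing = [c for c in ("doy", "t_mean") if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    w = weather.sort_values("doy").reset_index(drop=True)
    if np.any(np.diff(w["doy"].to_numpy()) != 1):
        raise ValueError("weather days must be contiguous (daily)")
    if {"t_min", "t_max"}.issubset(w.columns):
        bad = (w["t_min"] > w["t_mean"]) | (w["t_mean"] > w["t_max"])
        if bad.any():
            raise ValueError(
                f"t_min <= t_mean <= t_max violated on {int(bad.sum())} days"
            )
    if "snow_depth_cm" in w.columns and (w["snow_depth_cm"].dropna() < 0).any():
        raise ValueError("snow depth must be >= 0")
    return w


@dataclass(frozen=True)
class SeasonSegmentation:
    """Season start DOYs (None where the condition is never met)."""

    spring: int | None
    summer: int | None
    autumn: int | None
    winter: int | None
    run_length: int

    def as_dict(self) -> dict:
        return {
            "spring": self.spring,
            "summer": self.summer,
            "autumn": self.autumn,
            "winter": self.winter,
            "run_length": self.run_length,
        }


def _first_run_start(mask: np.ndarray, n: int, from_idx: int) -> int | None:
    """Index of the first run of >= n consecutive True at or after from_idx."""
    run = 0
    for i in range(from_idx, mask.size):
        run = run + 1 if mask[i] else 0
        if run >= n:
            return i - n + 1
    return None


def segment_thermal_seasons(weather: pd.DataFrame, run_length: int = 5) -> SeasonSegmentation:
    """Assign thermal-season start days from daily mean temperature.

    Spring, summer and autumn form a strict sequence (summer is only
    meaningful after spring, autumn after summer) because the cold-side
    thresholds are implied by the warm-side ones: a sub-zero winter day
    also satisfies autumn's "below +10 °C".  Winter (< 0 °C) is searched
    after the last assigned season start, or from the start of the series
    when no warm season ever established — a year that never thaws is
    winter throughout.
    """
    if run_length < 1:
        raise ValueError("run length must be >= 1")
    w = validate_weather(weather)
    t = w["t_mean"].to_numpy(dtype=float)
    doys = w["doy"].to_numpy(dtype=int)
    n = run_length

    spring = _first_run_start(t > 0.0, n, 0)
    summer = _first_run_start(t > 10.0, n, spring + 1) if spring is not None else None
    autumn = _first_run_start(t < 10.0, n, summer + 1) if summer is not None else None
    last_assigned = max((i for i in (spring, summer, autumn) if i is not None),
                        default=-1)
    winter = _first_run_start(t < 0.0, n, last_assigned + 1)

    as_doy = lambda idx: None if idx is None else int(doys[idx])
    return SeasonSegmentation(
        spring=as_doy(spring), summer=as_doy(summer),
        autumn=as_doy(autumn), winter=as_doy(winter), run_length=n,
    )


# ---------------------------------------------------------------------------
# Snow events and growing-season covariates
# ---------------------------------------------------------------------------

def snowmelt_day(weather: pd.DataFrame, segmentation: SeasonSegmentation,
                 persist_days: int = 7) -> int | None:
    """First (spring-onwards) snow-free day followed by >= persist_days snow-free days."""
    w = validate_weather(weather)
    snow = w["snow_depth_cm"].to_numpy(dtype=float)
    doys = w["doy"].to_numpy(dtype=int)
    start_doy = segmentation.spring if segmentation.spring is not None else doys[0]
    from_idx = int(np.searchsorted(doys, start_doy))
    free = np.nan_to_num(snow, nan=0.0) <= 0
    idx = _first_run_start(free, persist_days, from_idx)
    return None if idx is None else int(doys[idx])


def first_snowfall_day(weather: pd.DataFrame, segmentation: SeasonSegmentation,
                       persist_days: int = 7, min_depth_cm: float = 1.0) -> int | None:
    """First autumn/winter day with snow >= min_depth_cm persisting >= persist_days."""
    w = validate_weather(weather)
    snow = np.nan_to_num(w["snow_depth_cm"].to_numpy(dtype=float), nan=0.0)
    doys = w["doy"].to_numpy(dtype=int)
    start_doy = segmentation.autumn or segmentation.winter
    from_idx = 0 if start_doy is None else int(np.searchsorted(doys, start_doy))
    idx = _first_run_start(snow >= min_depth_cm, persist_days, from_idx)
    return None if idx is None else int(doys[idx])


def effective_temperature_sum(weather: pd.DataFrame, start_doy: int | None,
                              doy: int, t_base: float = 5.0) -> float:
    """Σ max(0, t_mean − t_base) from the growing-season start through doy.

    0 when doy precedes the growing-season start (or the season never
    started).
    """
    if start_doy is None or doy < start_doy:
        return 0.0
    w = validate_weather(weather)
    sel = (w["doy"] >= start_doy) & (w["doy"] <= doy)
    t = w.loc[sel, "t_mean"].to_numpy(dtype=float)
    return float(np.maximum(0.0, t - t_base).sum())


def growing_season_variables(weather: pd.DataFrame, segmentation: SeasonSegmentation,
                             doys, t_base: float = 5.0, persist_days: int = 7,
                             min_snow_depth_cm: float = 1.0) -> pd.DataFrame:
    """Per-DOY covariate table.

    Columns: days_post_snowmelt, days_prior_first_snowfall,
    days_from_growing_season_start, effective_temperature_sum.  Counters
    are null (pd.NA) before the defining event.
    """
    melt = snowmelt_day(weather, segmentation, persist_days)
    snowfall = first_snowfall_day(weather, segmentation, persist_days, min_snow_depth_cm)
    start = segmentation.spring
    rows = []
    for doy in np.atleast_1d(np.asarray(doys, dtype=int)):
        doy = int(doy)
        rows.append({
            "doy": doy,
            "days_post_snowmelt": doy - melt if melt is not None and doy >= melt else pd.NA,
            "days_prior_first_snowfall": (
                snowfall - doy if snowfall is not None and doy <= snowfall else pd.NA
            ),
            "days_from_growing_season_start": (
                doy - start if start is not None and doy >= start else pd.NA
            ),
            "effective_temperature_sum": effective_temperature_sum(
                weather, start, doy, t_base
            ),
        })
    return pd.DataFrame(rows)


def correlate_weather_iflav(iflav_by_doy: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of mean I_flav against each weather covariate.

    ``iflav_by_doy`` is indexed by DOY; covariates as produced by
    :func:`growing_season_variables`.  Covariates with fewer than 3 paired
    observations or zero variance give null rows.
    """
    from .trends import pearson_r_with_test

    cov = covariates.set_index("doy")
    out = []
    for name in cov.columns:
        pair = pd.concat([iflav_by_doy.rename("iflav"), cov[name].rename("x")],
                         axis=1, join="inner").dropna()
        res = None
        if len(pair) >= 3:
            res = pearson_r_with_test(pair["x"].astype(float).to_numpy(),
                                      pair["iflav"].astype(float).to_numpy())
        if res is None or res.r is None:
            out.append({"covariate": name, "n": len(pair), "r": pd.NA,
                        "p": pd.NA, "bracket": pd.NA})
        else:
            out.append({"covariate": name, "n": res.n, "r": res.r,
                        "p": res.p, "bracket": res.bracket})
    return pd.DataFrame(out)
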