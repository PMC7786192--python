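"""Temperature-humidity index (THI) from weather records.

THI combines daily maximum temperature and mean relative humidity into a
single heat-load index, the standard environmental gradient for heat-stress
studies in cattle:

    THI = (1.8 T + 32) - (0.55 - 0.0055 H) (1.8 T - 26.8)

with T in degrees Celsius and H in percent.  Each animal is assigned the THI
of the weather-station window preceding its slaughter date (by default the
15-45 day pre-slaughter period, the interval most relevant to carcass
quality), and the per-animal values are standardized to zero mean and unit
variance before entering any reaction-norm model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_thi",
    "window_aggregate",
    "animal_thi",
    "read_weather",
    "read_animals",
]

#: Temperature (deg C) at which THI is independent of humidity (1.8 T = 26.8).
THI_PIVOT_T = 26.8 / 1.8


class DegenerateCovariateError(ValueError):
    """Raised when the environmental covariate has zero variance."""


def compute_thi(t_max, rh_mean):
    """Temperature-humidity index from daily maximum temperature and humidity.

    Parameters
    ----------
    t_max : float or array-like
        Average daily maximum temperature, degrees Celsius.
    rh_mean : float or array-like
        Average relative humidity, percent, in [0, 100].

    Returns
    -------
    float or ndarray
        THI in index units.
    """
    t = np.asarray(t_max, dtype=float)
    h = np.asarray(rh_mean, dtype=float)
    if np.any(h < 0) or np.any(h > 100):
        raise ValueError("relative humidity must lie in [0, 100]")
    thi = (1.8 * t + 32.0) - (0.55 - 0.0055 * h) * (1.8 * t - 26.8)
    if np.ndim(t_max) == 0 and np.ndim(rh_mean) == 0:
        return float(thi)
    return thi


def read_weather(path) -> pd.DataFrame:
    """Read a weather table (TSV: station_id, date, t_max, rh_mean)."""
    df = pd.read_csv(path, sep="\t", parse_dates=["date"])
    return validate_weather(df)


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "date", "t_max", "rh_mean"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    if weather["rh_mean"].lt(0).any() or weather["rh_mean"].gt(100).any():
        raise ValueError("rh_mean outside [0, 100]")
    if weather.duplicated(["station_id", "date"]).any():
        raise ValueError("duplicate (station_id, date) rows in weather table")
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


def read_animals(path) -> pd.DataFrame:
    """Read an animal table (TSV with animal_id, farm_location, slaughter_date, ...)."""
    return pd.read_csv(path, sep="\t", parse_dates=["birth_date", "slaughter_date"])


def window_aggregate(
    weather: pd.DataFrame,
    station,
    slaughter_date,
    window_start_days: int = 45,
    window_end_days: int = 15,
):
    """Mean temperature and humidity over a pre-slaughter window.

    The window covers calendar days d with
    ``slaughter_date - window_start_days <= d <= slaughter_date - window_end_days``,
    both endpoints inclusive.

    Returns
    -------
    (t_avg, h_avg) : tuple of float
    """
    if not window_start_days > window_end_days >= 0:
        raise ValueError("require window_start_days > window_end_days >= 0")
    slaughter_date = pd.Timestamp(slaughter_date)
    lo = slaughter_date - pd.Timedelta(days=int(window_start_days))
    hi = slaughter_date - pd.Timedelta(days=int(window_end_days))
    sub = weather[
        (weather["station_id"] == station)
        & (weather["date"] >= lo)
        & (weather["date"] <= hi)
    ]
    if len(sub) == 0:
        raise LookupError(
            f"no weather records for station {station!r} in window "
            f"[{lo.date()}, {hi.date()}]"
        )
    return float(sub["t_max"].mean()), float(sub["rh_mean"].mean())


def _whole_period_means(weather, station, birth_date, slaughter_date, monthly):
    lo, hi = pd.Timestamp(birth_date), pd.Timestamp(slaughter_date)
    sub = weather[
        (weather["station_id"] == station)
        & (weather["date"] >= lo)
        & (weather["date"] <= hi)
    ]
    if len(sub) == 0:
        raise LookupError(f"no weather records for station {station!r} in growth period")
    if monthly:
        # average within calendar month first, then across months
        bym = sub.groupby(sub["date"].dt.to_period("M"))[["t_max", "rh_mean"]].mean()
        return float(bym["t_max"].mean()), float(bym["rh_mean"].mean())
    return float(sub["t_max"].mean()), float(sub["rh_mean"].mean())


def animal_thi(
    weather: pd.DataFrame,
    animals: pd.DataFrame,
    station_map: dict | None = None,
    window_start_days: int = 45,
    window_end_days: int = 15,
    whole_period: bool = False,
    monthly: bool = True,
) -> pd.DataFrame:
    """Per-animal raw THI over the aggregation window, plus its z-score.

    Parameters
    ----------
    weather : DataFrame
        Validated weather table.
    animals : DataFrame
        Must carry ``animal_id``, ``farm_location`` and ``slaughter_date``
        (and ``birth_date`` when ``whole_period``).
    station_map : dict, optional
        farm_location -> station_id.  Defaults to the identity mapping (farm
        locations that are themselves station ids).
    whole_period : bool
        Aggregate from birth to slaughter instead of the pre-slaughter
        window; with ``monthly`` the series is averaged per calendar month
        first.

    Returns
    -------
    DataFrame with columns ``animal_id``, ``raw_thi``, ``c`` where ``c`` is
    the population-sd z-score of ``raw_thi`` over the supplied animals.
    """
    weather = validate_weather(weather)
    stations = set(weather["station_id"])
    raw = np.empty(len(animals))
    for k, row in enumerate(animals.itertuples(index=False)):
        loc = row.farm_location
        station = station_map[loc] if station_map is not None else loc
        if station not in stations:
            raise LookupError(
                f"animal {row.animal_id!r}: farm location {loc!r} maps to "
                f"unknown station {station!r}"
            )
        try:
            if whole_period:
                t_avg, h_avg = _whole_period_means(
                    weather, station, row.birth_date, row.slaughter_date, monthly
                )
            else:
                t_avg, h_avg = window_aggregate(
                    weather, station, row.slaughter_date,
                    window_start_days, window_end_days,
                )
        except LookupError as err:
            raise LookupError(f"animal {row.animal_id!r}: {err}") from None
        raw[k] = compute_thi(t_avg, h_avg)
    return pd.DataFrame(
        {
            "animal_id": animals["animal_id"].to_numpy(),
            "raw_thi": raw,
            "c": standardize_covariate(raw),
        }
    )


def standardize_covariate(raw_thi) -> np.ndarray:
    """Population-sd z-score of the raw covariate (mean 0, sd 1, ddof=0)."""
    x = np.asarray(raw_thi, dtype=float)
    sd = x.std()  # population convention, matches genotype standardization
    if sd == 0.0:
        raise DegenerateCovariateError("environmental covariate has zero variance")
    return (x - x.mean()) / sd
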