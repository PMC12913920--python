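"""Logger time-series processing and annual microclimate summaries.

Raw loggers record temperature every 15 minutes at three levels: soil at
-8 cm, near-ground air at 15 cm, and air at 200 cm. This module calibrates
the raw series with fixed per-sensor offsets (derived from a co-location
period), applies deterministic quality screens, and reduces each site's
year of readings to the nine standard annual variables:

======================  =======================================================
abbreviation            meaning
======================  =======================================================
T.soil_8_cm.mean        annual mean soil temperature
T.air_15_cm.mean        annual mean near-ground temperature
T.air_15_cm.max.95p     95th percentile of daily maximum near-ground temps
T.air_15_cm.min.5p      5th percentile of daily minimum near-ground temps
T.air_15_cm.GDD5        growing degree days above 5 degC, near-ground
T.air_200_cm.mean       annual mean air temperature
T.air_200_cm.max.95p    95th percentile of daily maximum air temps
T.air_200_cm.min.5p     5th percentile of daily minimum air temps
T.air_200_cm.GDD5       growing degree days above 5 degC, air
======================  =======================================================

Quantiles use the linear-interpolation ("type 7") definition; calendar days
are cut at a fixed UTC+1 offset (no daylight saving); both choices are
configurable constants here because the field conventions vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "TemperatureSeries",
    "SensorCalibration",
    "MicroclimateSummary",
    "QCConfig",
    "SummaryConfig",
    "compute_offsets",
    "apply_calibration",
    "qc_screen",
    "daily_aggregate",
    "annual_mean",
    "percentile_extreme",
    "gdd5",
    "summarize_site",
    "SUMMARY_VARIABLES",
    "read_series_csv",
    "summaries_to_frame",
]

STEP = pd.Timedelta(minutes=15)
READINGS_PER_DAY = 96
PLAUSIBLE_RANGE = (-45.0, 60.0)


class Level(str, Enum):
    """Measurement level of a sensor."""

    soil_8cm = "soil_8cm"
    air_15cm = "air_15cm"
    air_200cm = "air_200cm"


#: Table of the nine annual variables: abbreviation -> (level, statistic)
SUMMARY_VARIABLES: dict[str, tuple[Level, str]] = {
    "T.soil_8_cm.mean": (Level.soil_8cm, "mean"),
    "T.air_15_cm.mean": (Level.air_15cm, "mean"),
    "T.air_15_cm.max.95p": (Level.air_15cm, "max95p"),
    "T.air_15_cm.min.5p": (Level.air_15cm, "min5p"),
    "T.air_15_cm.GDD5": (Level.air_15cm, "gdd5"),
    "T.air_200_cm.mean": (Level.air_200cm, "mean"),
    "T.air_200_cm.max.95p": (Level.air_200cm, "max95p"),
    "T.air_200_cm.min.5p": (Level.air_200cm, "min5p"),
    "T.air_200_cm.GDD5": (Level.air_200cm, "gdd5"),
}


@dataclass
class TemperatureSeries:
    """One sensor's 15-minute temperature record.

    ``timestamps`` must be strictly increasing on a constant 15-minute
    lattice; gaps are represented by missing rows, never by irregular steps.
    ``qc_ok`` flags readings kept after screening.
    """

    site_id: str
    sensor_id: str
    level: Level
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    qc_ok: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.qc_ok is None:
            self.qc_ok = np.ones(len(self.values), dtype=bool)
        else:
            self.qc_ok = np.asarray(self.qc_ok, dtype=bool)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(deltas % STEP.value):
                raise ValueError("timestamps must lie on the 15-minute lattice")

    def ok_values(self) -> np.ndarray:
        return self.values[self.qc_ok]

    def ok_timestamps(self) -> pd.DatetimeIndex:
        return self.timestamps[self.qc_ok]


@dataclass(frozen=True)
class SensorCalibration:
    """Fixed additive bias of one sensor, in degC."""

    sensor_id: str
    offset: float


@dataclass(frozen=True)
class MicroclimateSummary:
    site_id: str
    variable: str
    value: float
    n_days_used: int


@dataclass(frozen=True)
class QCConfig:
    value_min: float = PLAUSIBLE_RANGE[0]
    value_max: float = PLAUSIBLE_RANGE[1]
    #: consecutive identical readings beyond this count are a flatline (7 d)
    flatline_run: int = 672


@dataclass(frozen=True)
class SummaryConfig:
    #: fraction of the 96 daily readings required to keep a day
    day_completeness: float = 0.9
    #: fraction of the 365-day year's readings required for annual stats
    year_coverage: float = 0.9
    #: minimum qualifying days for the daily-percentile extremes
    min_days: int = 30
    #: fixed local-time offset (hours east of UTC) for the day boundary
    utc_offset_hours: float = 1.0
    gdd_base: float = 5.0


def compute_offsets(group: list[TemperatureSeries]) -> list[SensorCalibration]:
    """Per-sensor offsets from a co-location (calibration) period.

    Each offset is the mean, over the timestamps shared by the whole group,
    of the focal sensor's reading minus the mean of the other sensors'
    simultaneous readings. Requires at least three sensors and at least
    24 h of common overlap.
    """
    if len(group) < 3:
        raise ValueError("offset calibration needs at least 3 co-located sensors")
    common = group[0].ok_timestamps()
    for s in group[1:]:
        common = common.intersection(s.ok_timestamps())
    if len(common) == 0 or common[-1] - common[0] < pd.Timedelta(hours=24):
        raise ValueError("co-location overlap must span at least 24 hours")
    mat = np.empty((len(group), len(common)))
    for i, s in enumerate(group):
        idx = s.timestamps.get_indexer(common)
        mat[i] = s.values[idx]
    others_mean = (mat.sum(axis=0) - mat) / (len(group) - 1)
    offsets = (mat - others_mean).mean(axis=1)
    return [SensorCalibration(s.sensor_id, float(o)) for s, o in zip(group, offsets)]


def apply_calibration(series: TemperatureSeries, cal: SensorCalibration) -> TemperatureSeries:
    """Subtract the sensor's fixed offset from every retained reading."""
    if series.sensor_id != cal.sensor_id:
        raise ValueError(
            f"calibration for sensor {cal.sensor_id!r} applied to {series.sensor_id!r}"
        )
    vals = series.values.copy()
    vals[series.qc_ok] = vals[series.qc_ok] - cal.offset
    return replace(series, values=vals, qc_ok=series.qc_ok.copy())


def qc_screen(series: TemperatureSeries, limits: QCConfig = QCConfig()) -> TemperatureSeries:
    """Deterministic quality screen: physical range and flatline runs.

    Readings outside the plausible range, and runs of more than
    ``limits.flatline_run`` consecutive identical readings (a stuck sensor),
    are flagged removed. Pure flagging; values are untouched.
    """
    ok = series.qc_ok.copy()
    vals = series.values
    ok &= (vals >= limits.value_min) & (vals <= limits.value_max)
    if len(vals) > limits.flatline_run:
        # run-length encode consecutive equal values
        change = np.flatnonzero(np.diff(vals) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vals)]))
        for s, e in zip(starts, ends):
            if e - s > limits.flatline_run:
                ok[s:e] = False
    return replace(series, values=vals.copy(), qc_ok=ok)


def _local_days(ts: pd.DatetimeIndex, cfg: SummaryConfig) -> np.ndarray:
    shifted = ts + pd.Timedelta(hours=cfg.utc_offset_hours)
    return shifted.normalize().asi8


def daily_aggregate(
    series: TemperatureSeries, cfg: SummaryConfig = SummaryConfig()
) -> pd.DataFrame:
    """Per-calendar-day min/max/mean over retained readings.

    Days with fewer than ``day_completeness * 96`` retained readings are
    dropped. The day boundary uses the fixed local-time offset of ``cfg``.
    """
    ts = series.ok_timestamps()
    vals = series.ok_values()
    if len(ts) == 0:
        return pd.DataFrame(
            columns=["day", "daily_min", "daily_max", "daily_mean", "n_readings"]
        )
    days = _local_days(ts, cfg)
    df = pd.DataFrame({"day": days, "value": vals})
    agg = df.groupby("day")["value"].agg(
        daily_min="min", daily_max="max", daily_mean="mean", n_readings="count"
    )
    agg = agg[agg["n_readings"] >= cfg.day_completeness * READINGS_PER_DAY]
    out = agg.reset_index()
    out["day"] = pd.to_datetime(out["day"])
    return out


def _year_window(series: TemperatureSeries) -> tuple[pd.Timestamp, pd.Timestamp]:
    start = series.timestamps[0]
    return start, start + pd.Timedelta(days=365)


def _year_ok(series: TemperatureSeries, cfg: SummaryConfig):
    start, end = _year_window(series)
    in_win = (series.timestamps >= start) & (series.timestamps < end)
    ok = in_win & series.qc_ok
    return series.values[ok], ok.sum()


def annual_mean(series: TemperatureSeries, cfg: SummaryConfig = SummaryConfig()) -> float:
    """Arithmetic mean of retained readings over the 365-day window."""
    vals, n = _year_ok(series, cfg)
    expected = 365 * READINGS_PER_DAY
    if n < cfg.year_coverage * expected:
        raise ValueError(
            f"annual coverage {n}/{expected} readings "
            f"({n / expected:.1%}) below the {cfg.year_coverage:.0%} threshold"
        )
    return float(vals.mean())


def percentile_extreme(daily: pd.DataFrame, which: str, min_days: int = 30) -> float:
    """Robust annual extreme from the daily table.

    ``max95p`` is the 95th percentile of daily maxima; ``min5p`` the 5th
    percentile of daily minima. Linear-interpolation quantiles.
    """
    if len(daily) < min_days:
        raise ValueError(f"only {len(daily)} qualifying days; need >= {min_days}")
    if which == "max95p":
        return float(np.percentile(daily["daily_max"].to_numpy(), 95))
    if which == "min5p":
        return float(np.percentile(daily["daily_min"].to_numpy(), 5))
    raise ValueError(f"unknown extreme {which!r}")


def gdd5(series: TemperatureSeries, cfg: SummaryConfig = SummaryConfig()) -> float:
    """Growing degree days: sum of exceedances over 5 degC divided by 96.

    Equivalent to the time integral of max(0, T - 5) in degC.day when the
    series has the full 15-minute resolution.
    """
    vals, n = _year_ok(series, cfg)
    expected = 365 * READINGS_PER_DAY
    if n < cfg.year_coverage * expected:
        raise ValueError(f"annual coverage {n / expected:.1%} below threshold")
    return float(np.maximum(0.0, vals - cfg.gdd_base).sum() / READINGS_PER_DAY)


def summarize_site(
    series_list: list[TemperatureSeries], cfg: SummaryConfig = SummaryConfig()
) -> list[MicroclimateSummary]:
    """All computable annual variables for one site.

    With all three levels present this yields exactly nine summaries; the
    soil level contributes only the mean, the two air levels contribute
    mean, the two percentile extremes, and GDD5 each.
    """
    if not series_list:
        raise ValueError("no series supplied")
    site_id = series_list[0].site_id
    by_level: dict[Level, TemperatureSeries] = {}
    for s in series_list:
        if s.site_id != site_id:
            raise ValueError("summarize_site expects series from a single site")
        by_level[Level(s.level)] = s
    out: list[MicroclimateSummary] = []
    for var, (level, stat) in SUMMARY_VARIABLES.items():
        s = by_level.get(level)
        if s is None:
            continue
        daily = daily_aggregate(s, cfg)
        n_days = len(daily)
        if stat == "mean":
            value = annual_mean(s, cfg)
        elif stat == "gdd5":
            value = gdd5(s, cfg)
        else:
            value = percentile_extreme(daily, stat, cfg.min_days)
        out.append(MicroclimateSummary(site_id, var, value, n_days))
    return out


def read_series_csv(path) -> list[TemperatureSeries]:
    """Read long-format logger CSV: site_id, sensor_id, level, timestamp, temperature_C."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (site, sensor, level), g in df.groupby(["site_id", "sensor_id", "level"], sort=True):
        g = g.sort_values("timestamp")
        out.append(
            TemperatureSeries(
                str(site),
                str(sensor),
                Level(level),
                pd.DatetimeIndex(g["timestamp"]),
                g["temperature_C"].to_numpy(),
            )
        )
    return out


def summaries_to_frame(summaries: list[MicroclimateSummary]) -> pd.DataFrame:
    """Tidy table of summaries, one row per (site, variable)."""
    return pd.DataFrame(
        [(s.site_id, s.variable, s.value, s.n_days_used) for s in summaries],
        columns=["site_id", "variable", "value", "n_days_used"],
    )
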