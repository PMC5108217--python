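"""Thermal covariates from temperature-logger series.

Larval fish traits measured at emergence depend on the water temperatures
experienced while larvae reside in rearing chambers.  Two covariates summarise
that exposure for an individual residence interval:

* cumulative **degree-days**: ``sum over calendar days of
  max(daily mean temperature - T0, 0) * (fraction of the day inside the
  interval)``, with threshold ``T0`` in deg C (0 deg C for lake sturgeon, whose
  growth is essentially nil at freezing);
* the time-weighted **mean temperature** over the interval.

The logger series is treated as a step function: each reading holds until the
next one (last-observation-carried-forward), which matches how interval
loggers report and makes every integral exactly computable.  The "daily
temperature" entering degree-days is the plain mean of the readings that fall
within each calendar day; partial first/last days are pro-rated by the time
fraction of the day covered by the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ResidenceInterval",
    "DegreeDayParams",
    "degree_days",
    "mean_temperature",
]

_NS_PER_DAY = 86_400_000_000_000


class TemperatureSeries:
    """Ordered timestamped deg-C readings.

    Parameters
    ----------
    timestamps : array-like of datetime64 / parseable timestamps
        Strictly increasing reading times.
    temperatures : array-like of float
        Finite temperatures in deg C, one per timestamp.
    """

    def __init__(self, timestamps, temperatures) -> None:
        ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps)))
        temps = np.asarray(temperatures, dtype=float)
        if len(ts) != len(temps):
            raise ValueError("timestamps and temperatures differ in length")
        if len(ts) == 0:
            raise ValueError("empty temperature series")
        if not np.all(np.diff(ts.asi8) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(temps)):
            raise ValueError("temperatures must be finite")
        self.timestamps = ts
        self.temperatures = temps

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.timestamps[0], self.timestamps[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "temperature_c": self.temperatures}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TemperatureSeries":
        missing = {"timestamp", "temperature_c"} - set(frame.columns)
        if missing:
            raise ValueError(f"temperature table missing columns: {sorted(missing)}")
        return cls(frame["timestamp"], frame["temperature_c"])

    def daily_means(self) -> pd.Series:
        """Mean of the readings within each calendar day, indexed by date."""
        frame = self.to_frame()
        return frame.groupby(frame["timestamp"].dt.normalize())["temperature_c"].mean()

    def covers(self, interval: "ResidenceInterval") -> bool:
        first, last = self.span
        return first <= interval.start and interval.end <= last


@dataclass(frozen=True)
class ResidenceInterval:
    """Time an individual spent in a rearing chamber."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.end > self.start:
            raise ValueError("residence interval requires end > start")

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).value / _NS_PER_DAY


@dataclass(frozen=True)
class DegreeDayParams:
    """Threshold temperature T0 (deg C) below which no thermal units accrue."""

    threshold_c: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_c):
            raise ValueError("threshold must be finite")


def _require_coverage(series: TemperatureSeries, interval: ResidenceInterval) -> None:
    if not series.covers(interval):
        first, last = series.span
        raise ValueError(
            f"interval [{interval.start}, {interval.end}] outside series span "
            f"[{first}, {last}]"
        )


def degree_days(
    series: TemperatureSeries,
    interval: ResidenceInterval,
    params: DegreeDayParams = DegreeDayParams(),
) -> float:
    """Cumulative degree-days over a residence interval.

    Sums, over every calendar day the interval touches,
    ``max(daily mean - T0, 0)`` weighted by the fraction of that day inside
    the interval.  Additive over disjoint sub-intervals and non-increasing in
    the threshold.
    """
    _require_coverage(series, interval)
    daily = series.daily_means()
    first_day = interval.start.normalize()
    # the day containing `end` contributes unless `end` is exactly midnight
    last_day = (interval.end - pd.Timedelta(1, "ns")).normalize()
    total = 0.0
    for day in pd.date_range(first_day, last_day, freq="D"):
        if day not in daily.index:
            raise ValueError(f"no temperature readings on {day.date()}")
        day_end = day + pd.Timedelta(1, "D")
        overlap_ns = (
            min(interval.end, day_end) - max(interval.start, day)
        ).value
        frac = overlap_ns / _NS_PER_DAY
        total += max(daily[day] - params.threshold_c, 0.0) * frac
    return total


def mean_temperature(series: TemperatureSeries, interval: ResidenceInterval) -> float:
    """Time-weighted mean temperature over the interval (step interpolation)."""
    _require_coverage(series, interval)
    t = series.timestamps.asi8
    temps = series.temperatures
    lo = interval.start.value
    hi = interval.end.value
    # segment i spans [t[i], t[i+1]); clip to the interval
    seg_start = np.maximum(t[:-1], lo)
    seg_end = np.minimum(t[1:], hi)
    weights = np.clip(seg_end - seg_start, 0, None).astype(float)
    total_w = weights.sum()
    if total_w <= 0:  # degenerate: interval collapses onto a single reading
        idx = int(np.searchsorted(t, lo, side="right") - 1)
        return float(temps[idx])
    return float(np.dot(temps[:-1], weights) / total_w)
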