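"""Sensor-stream containers and conversion to regular hourly grids.

All rhythm metrics consume :class:`HourlySeries`: one value per whole hour
with a boolean availability mask.  Event streams (calls, SMS, screen
on/off, ...) become counts per hour; continuous streams (light, sound,
acceleration, ...) become hourly means, with empty hours masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorStream", "HourlySeries", "bin_hourly", "fill_short_gaps"]


@dataclass
class SensorStream:
    """Raw timestamped data for one modality of one patient.

    Parameters
    ----------
    modality : str
        Modality name (e.g. ``"light"``, ``"screen"``).
    kind : {"event", "continuous"}
        Events carry timestamps only; continuous streams carry a value
        per sample.
    timestamps : pandas.DatetimeIndex
        Sample times, not necessarily sorted.
    values : numpy.ndarray or None
        Sample values for continuous streams, ``None`` for events.
    """

    modality: str
    kind: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("event", "continuous"):
            raise ValueError(f"unknown stream kind {self.kind!r}")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.kind == "continuous":
            if self.values is None:
                raise ValueError("continuous stream requires values")
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != len(self.timestamps):
                raise ValueError("values and timestamps length mismatch")
        if not self.timestamps.is_monotonic_increasing:
            order = np.argsort(self.timestamps.asi8, kind="stable")
            self.timestamps = self.timestamps[order]
            if self.values is not None:
                self.values = self.values[order]

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class HourlySeries:
    """A regular hourly grid: one value per whole hour plus a mask.

    ``mask[i]`` is True when hour ``i`` carries observed data.  Masked
    entries are excluded from every statistic downstream.
    """

    start: pd.Timestamp
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).floor("h")
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.values):
            raise ValueError("mask and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> pd.Timestamp:
        """First hour after the series."""
        return self.start + pd.Timedelta(hours=len(self))

    def hour_of_day(self) -> np.ndarray:
        """Hour-of-day (0..23) label for every grid position."""
        return (self.start.hour + np.arange(len(self))) % 24

    def slice_hours(self, start: pd.Timestamp, n_hours: int) -> "HourlySeries":
        """Extract ``n_hours`` starting at ``start``; out-of-range hours
        come back masked."""
        start = pd.Timestamp(start).floor("h")
        offset = int((start - self.start) / pd.Timedelta(hours=1))
        values = np.zeros(n_hours)
        mask = np.zeros(n_hours, dtype=bool)
        lo = max(0, -offset)
        hi = min(n_hours, len(self) - offset)
        if hi > lo:
            values[lo:hi] = self.values[offset + lo : offset + hi]
            mask[lo:hi] = self.mask[offset + lo : offset + hi]
        return HourlySeries(start=start, values=values, mask=mask)

    def coverage(self) -> float:
        return float(self.mask.mean()) if len(self) else 0.0


def bin_hourly(
    stream: SensorStream,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> HourlySeries:
    """Bin a sensor stream onto the hourly grid.

    Event streams become counts per hour (zero-event hours are valid
    zeros).  Continuous streams become the mean of the samples in each
    hour; hours with no samples are masked.

    Parameters
    ----------
    stream : SensorStream
    span : (start, end), optional
        Grid extent.  Required for empty streams; defaults to the hours
        spanned by the data.

    Returns
    -------
    HourlySeries
    """
    if span is not None:
        start = pd.Timestamp(span[0]).floor("h")
        end = pd.Timestamp(span[1]).ceil("h")
    elif len(stream) > 0:
        start = stream.timestamps[0].floor("h")
        end = stream.timestamps[-1].floor("h") + pd.Timedelta(hours=1)
    else:
        raise ValueError("empty stream requires an explicit span")

    n_hours = int((end - start) / pd.Timedelta(hours=1))
    if n_hours <= 0:
        raise ValueError("span must cover at least one hour")

    if len(stream) == 0:
        values = np.zeros(n_hours)
        mask = np.zeros(n_hours, dtype=bool)
        return HourlySeries(start=start, values=values, mask=mask)

    idx = ((stream.timestamps.asi8 - start.value) // (3600 * 10**9)).astype(np.int64)
    keep = (idx >= 0) & (idx < n_hours)
    idx = idx[keep]

    if stream.kind == "event":
        values = np.bincount(idx, minlength=n_hours).astype(float)
        mask = np.ones(n_hours, dtype=bool)
    else:
        vals = stream.values[keep]
        counts = np.bincount(idx, minlength=n_hours)
        sums = np.bincount(idx, weights=vals, minlength=n_hours)
        mask = counts > 0
        values = np.zeros(n_hours)
        values[mask] = sums[mask] / counts[mask]
    return HourlySeries(start=start, values=values, mask=mask)


def fill_short_gaps(series: HourlySeries, max_gap: int = 3) -> HourlySeries:
    """Linearly interpolate across masked runs of length <= ``max_gap``
    that are bounded by observed hours; longer runs stay masked."""
    values = series.values.copy()
    mask = series.mask.copy()
    n = len(values)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            left, right = values[i - 1], values[j]
            for k in range(gap):
                values[i + k] = left + (right - left) * (k + 1) / (gap + 1)
            mask[i:j] = True
        i = j
    return HourlySeries(start=series.start, values=values, mask=mask)
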