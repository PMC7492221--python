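"""Windowed rhythm-feature extraction.

Each feature is named ``[Modality]⊗[Rhythm Metric]⊗[Window Length]``
(e.g. ``light⊗amplitude⊗2-day_window``) and carries a periodicity tag
(ultradian / circadian / infradian) determined by its metric.  Feature
vectors are extracted from the data segment between day ``d - w`` and
day ``d`` for every report date ``d`` and window length
``w ∈ {2, 4, 6, 8, 10, 12, 14}`` days, and assembled into one matrix
row per report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rhythm_mtl import metrics as rm
from rhythm_mtl.hourly import HourlySeries

__all__ = [
    "WINDOWS_DAYS",
    "SYMPTOMS",
    "FeatureName",
    "parse_feature_name",
    "categorize_periodicity",
    "metric_names_for",
    "canonical_feature_names",
    "extract_features",
    "build_feature_matrix",
]

SEP = "⊗"

#: Window lengths (days) of historical data per feature.
WINDOWS_DAYS = (2, 4, 6, 8, 10, 12, 14)

#: The ten momentary self-report items, in canonical order.
SYMPTOMS = (
    "depressed",
    "seeing_things",
    "harm",
    "voices",
    "sleep",
    "stressed",
    "think",
    "hopeful",
    "social",
    "calm",
)

_TEMPLATE_METRICS = (
    "mean_deviation",
    "median_deviation",
    "std_deviation",
    "prev_mean_deviation",
    "prev_median_deviation",
    "prev_std_deviation",
)

#: Modalities IS/IV apply to (continuous-valued streams only).
ISIV_MODALITIES = frozenset({"acceleration", "light", "sound"})


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier: modality, metric, window length."""

    modality: str
    metric: str
    window_days: int

    def __post_init__(self) -> None:
        if self.window_days not in WINDOWS_DAYS:
            raise ValueError(f"window {self.window_days} not in {WINDOWS_DAYS}")
        categorize_periodicity(self.metric)  # validates the metric

    @property
    def periodicity(self) -> str:
        return categorize_periodicity(self.metric)

    def __str__(self) -> str:
        return f"{self.modality}{SEP}{self.metric}{SEP}{self.window_days}-day_window"


def parse_feature_name(name: str) -> FeatureName:
    """Inverse of ``str(FeatureName)``."""
    parts = name.split(SEP)
    if len(parts) != 3 or not parts[2].endswith("-day_window"):
        raise ValueError(f"malformed feature name {name!r}")
    window = int(parts[2][: -len("-day_window")])
    return FeatureName(modality=parts[0], metric=parts[1], window_days=window)


def categorize_periodicity(metric: str) -> str:
    """Map a rhythm metric to its periodicity class.

    Multiscale entropy and short-period (< ~20 h) spectral power are
    ultradian; M10, L5, relative amplitude, template deviation, IS, IV
    and 20–30 h spectral power are circadian; longer-period spectral
    power is infradian.
    """
    if metric.endswith("-hour_MSE"):
        return "ultradian"
    if metric.endswith("-hour_PSD"):
        period = float(metric[: -len("-hour_PSD")])
        if period <= 20:
            return "ultradian"
        if period < 30:
            return "circadian"
        return "infradian"
    if metric in ("M10", "L5", "amplitude", "IS", "IV") or metric in _TEMPLATE_METRICS:
        return "circadian"
    raise ValueError(f"unknown rhythm metric {metric!r}")


def _psd_periods_for_window(window_days: int) -> tuple[float, ...]:
    """Listed periods that fit inside the window (period <= window hours)."""
    limit = window_days * 24
    return tuple(float(p) for p in rm.PSD_PERIODS_H if p <= limit)


def metric_names_for(modality: str, window_days: int) -> list[str]:
    """Canonical ordered metric list for one (modality, window) pair."""
    names = [f"{tau}-hour_MSE" for tau in rm.MSE_SCALES]
    names += [f"{p:g}-hour_PSD" for p in _psd_periods_for_window(window_days)]
    names += ["M10", "L5", "amplitude"]
    names += list(_TEMPLATE_METRICS)
    if modality in ISIV_MODALITIES:
        names += ["IS", "IV"]
    return names


def canonical_feature_names(
    modalities: tuple[str, ...], windows: tuple[int, ...] = WINDOWS_DAYS
) -> list[str]:
    """The fixed, ordered feature-column name sequence for a cohort."""
    names = []
    for w in windows:
        for modality in modalities:
            for metric in metric_names_for(modality, w):
                names.append(str(FeatureName(modality, metric, w)))
    return names


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _window_features(series: HourlySeries, modality: str, window_days: int) -> dict[str, float]:
    """All metrics on one already-sliced window."""
    out: dict[str, float] = {}
    mse = rm.multiscale_entropy(series)
    for tau, value in zip(rm.MSE_SCALES, mse):
        out[f"{tau}-hour_MSE"] = float(value)
    band = rm.psd_band_power(series, _psd_periods_for_window(window_days))
    for p, value in band.items():
        out[f"{p:g}-hour_PSD"] = float(value)
    m10, l5 = rm.m10_l5(series)
    out["M10"] = m10
    out["L5"] = l5
    out["amplitude"] = rm.relative_amplitude(m10, l5)
    dev = rm.template_deviation(series)
    for name, value in zip(_TEMPLATE_METRICS, dev):
        out[name] = float(value)
    if modality in ISIV_MODALITIES:
        out["IS"] = rm.interday_stability(series)
        out["IV"] = rm.intraday_variability(series)
    return out


def extract_features(
    hourly: dict[str, HourlySeries],
    ema_date: pd.Timestamp,
    window_days: int,
) -> dict[str, float]:
    """Feature vector for one report date and one window length.

    The window is ``[d - w, d)`` in whole days anchored at midnight of
    the report date ``d``.  A window that starts before a stream's
    first hour yields NaN for that stream's features.

    Parameters
    ----------
    hourly : dict
        Modality name -> full-span :class:`HourlySeries`.
    ema_date : timestamp-like
        The report date ``d``.
    window_days : int
    """
    anchor = pd.Timestamp(ema_date).normalize()
    start = anchor - pd.Timedelta(days=window_days)
    n_hours = window_days * 24
    out: dict[str, float] = {}
    for modality, series in hourly.items():
        prefix_ok = start >= series.start and anchor <= series.end
        if prefix_ok:
            window = series.slice_hours(start, n_hours)
            values = _window_features(window, modality, window_days)
        else:
            values = {m: float("nan") for m in metric_names_for(modality, window_days)}
        for metric, value in values.items():
            out[str(FeatureName(modality, metric, window_days))] = value
    return out


def build_feature_matrix(
    hourly: dict[str, HourlySeries],
    ema: pd.DataFrame,
    windows: tuple[int, ...] = WINDOWS_DAYS,
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-patient feature matrix and label matrix.

    One row per report date (all windows concatenated, canonical column
    order).  Rows with more than ``max_missing_fraction`` missing
    features are dropped; remaining missing values are imputed with the
    patient's per-feature median; features missing everywhere become 0.

    Parameters
    ----------
    hourly : dict
        Modality name -> full-span :class:`HourlySeries`.
    ema : DataFrame
        Indexed by report date with the ten item-score columns.

    Returns
    -------
    (X, Y) : DataFrames indexed by the retained report dates.

    Raises
    ------
    ValueError
        If every row is dropped.
    """
    if len(ema) == 0:
        raise ValueError("need at least one report")
    columns = canonical_feature_names(tuple(hourly.keys()), windows)
    rows = []
    for d in ema.index:
        row: dict[str, float] = {}
        for w in windows:
            row.update(extract_features(hourly, d, w))
        rows.append([row[c] for c in columns])
    X = pd.DataFrame(rows, index=ema.index, columns=columns, dtype=float)
    keep = X.isna().mean(axis=1) <= max_missing_fraction
    if not keep.any():
        raise ValueError("all report rows dropped for missing features")
    X = X.loc[keep]
    X = X.fillna(X.median())
    X = X.fillna(0.0)  # features missing in every retained row
    Y = ema.loc[keep].astype(float)
    return X, Y
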