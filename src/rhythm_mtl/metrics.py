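"""Rhythm metrics computed on hourly series.

Implements multiscale sample entropy, spectral band power, the
nonparametric circadian statistics M10/L5/relative amplitude,
deviation-from-template statistics, interday stability (IS) and
intraday variability (IV).  Every metric returns ``numpy.nan`` when its
minimum-data requirements are not met; callers treat NaN as "missing".

Conventions
-----------
* Sample entropy uses Chebyshev distance, template length ``m``,
  self-matches excluded, and a tolerance fixed from the SD of the
  original (scale-1) series across all coarse-graining scales.
* The periodogram is one-sided with power-spectrum scaling so the sum
  of the nonzero-frequency ordinates equals the variance of the
  (detrended) series.  The "band power" for a listed period integrates
  the ordinates whose frequency falls between the geometric midpoints
  to the neighbouring listed periods.
* M10/L5 and the 24-h template are computed on the hour-of-day mean
  profile of the window; M10/L5 runs are circular.
"""

from __future__ import annotations

import numpy as np

from rhythm_mtl.hourly import HourlySeries

__all__ = [
    "sample_entropy",
    "coarse_grain",
    "multiscale_entropy",
    "psd_periodogram",
    "psd_band_power",
    "daily_profile",
    "m10_l5",
    "relative_amplitude",
    "template_deviation",
    "interday_stability",
    "intraday_variability",
    "PSD_PERIODS_H",
    "MSE_SCALES",
    "MIN_COVERAGE",
]

#: Periods (hours) at which spectral band power is reported.
PSD_PERIODS_H = (2, 4, 8, 16, 20, 22, 27, 28, 32, 36, 64, 72, 128, 256, 512)

#: Coarse-graining scales (hours) for multiscale entropy.
MSE_SCALES = (1, 2, 3, 4, 5, 6)

#: Minimum fraction of unmasked hours a window must have.
MIN_COVERAGE = 0.7

_MIN_ENTROPY_POINTS = 10


# ---------------------------------------------------------------------------
# sample entropy / multiscale entropy
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(U(m+1)/U(m)) of a 1-D series.

    ``U(k)`` counts pairs of distinct length-``k`` templates within
    Chebyshev distance ``r``, both templates drawn from the first
    ``n - m`` positions so the two template lengths are counted over
    the same index set.

    Returns NaN when ``n <= m + 1`` or when either count is zero
    (e.g. a constant series with ``r == 0``).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if m < 1:
        raise ValueError("template length m must be >= 1")
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    if n <= m + 1:
        return float("nan")

    n_templates = n - m  # same count for both lengths

    # Chebyshev template distances built incrementally: the distance
    # matrix at length k+1 is the elementwise max of the length-k matrix
    # and the shifted pointwise distances.
    D = np.abs(x[:, None] - x[None, :])
    Mk = D  # length-1 template distances
    for k in range(1, m):
        Mk = np.maximum(Mk[:-1, :-1], D[k:, k:])
    Mk1 = np.maximum(Mk[:-1, :-1], D[m:, m:])

    def _pairs(M: np.ndarray) -> int:
        sub = M[:n_templates, :n_templates]
        return int((sub <= r).sum() - n_templates) // 2

    u_m = _pairs(Mk)
    u_m1 = _pairs(Mk1)
    if u_m == 0 or u_m1 == 0:
        return float("nan")
    return float(-np.log(u_m1 / u_m))


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Block-average a series at scale ``tau``; element ``j`` is the mean
    of block ``(j-1)*tau+1 .. j*tau``.  A trailing partial block is
    dropped."""
    if tau < 1:
        raise ValueError("scale tau must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < tau:
        raise ValueError("series shorter than scale")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def multiscale_entropy(
    series: HourlySeries,
    m: int = 2,
    r_factor: float = 0.25,
    scales: tuple[int, ...] = MSE_SCALES,
) -> np.ndarray:
    """Sample entropy of the coarse-grained series at each scale.

    The tolerance is ``r_factor * SD`` of the unmasked scale-1 series
    and is held fixed across scales.  Scales with too few points, or
    degenerate counts, yield NaN.
    """
    x = series.values[series.mask]
    out = np.full(len(scales), np.nan)
    if x.size < _MIN_ENTROPY_POINTS or series.coverage() < MIN_COVERAGE:
        return out
    sd = float(np.std(x))
    if sd == 0:
        return out
    r = r_factor * sd
    for i, tau in enumerate(scales):
        if x.size < tau:
            continue
        y = coarse_grain(x, tau)
        if y.size > m + 1:
            out[i] = sample_entropy(y, m=m, r=r)
    return out


# ---------------------------------------------------------------------------
# periodogram band power
# ---------------------------------------------------------------------------

def psd_periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of an hourly series.

    The series is linearly detrended.  Ordinates are scaled so that
    ``sum(power)`` over the returned (nonzero) frequencies equals the
    variance of the detrended series (Parseval).

    Returns
    -------
    freqs : ndarray
        Cycles per hour, excluding zero frequency.
    power : ndarray
    """
    from scipy.signal import detrend

    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    xd = detrend(x, type="linear")
    spec = np.fft.rfft(xd)
    power = np.abs(spec) ** 2 / n**2
    # fold negative frequencies; Nyquist term (even n) is unique
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0)
    return freqs[1:], power[1:]


def _band_edges(periods: tuple[float, ...]) -> list[tuple[float, float]]:
    """Frequency band per listed period, bounded by geometric midpoints
    to the adjacent listed periods (log-symmetric at the edges)."""
    p = np.sort(np.asarray(periods, dtype=float))
    edges = []
    for i, pi in enumerate(p):
        lo_p = np.sqrt(p[i - 1] * pi) if i > 0 else pi * np.sqrt(pi / p[i + 1])
        hi_p = np.sqrt(pi * p[i + 1]) if i < len(p) - 1 else pi * np.sqrt(pi / p[i - 1])
        edges.append((lo_p, hi_p))
    order = np.argsort(np.argsort(np.asarray(periods, dtype=float)))
    return [edges[k] for k in order]


def psd_band_power(
    series: HourlySeries,
    periods_h: tuple[float, ...] = PSD_PERIODS_H,
) -> dict[float, float]:
    """Integrated spectral power around each listed period.

    Masked hours are imputed with the mean of the unmasked hours before
    the FFT.  A period longer than the series, or a series below the
    coverage floor, yields NaN for that period.  Bands that contain no
    Fourier frequency get zero power.
    """
    n = len(series)
    out = {float(p): float("nan") for p in periods_h}
    if n < 4 or series.coverage() < MIN_COVERAGE:
        return out
    x = series.values.copy()
    if not series.mask.all():
        x[~series.mask] = x[series.mask].mean()
    freqs, power = psd_periodogram(x)
    for (lo_p, hi_p), p in zip(_band_edges(tuple(periods_h)), periods_h):
        if p > n:
            continue
        # period band (lo_p, hi_p] -> frequency band [1/hi_p, 1/lo_p)
        sel = (freqs >= 1.0 / hi_p) & (freqs < 1.0 / lo_p)
        out[float(p)] = float(power[sel].sum())
    return out


# ---------------------------------------------------------------------------
# 24-h profile statistics
# ---------------------------------------------------------------------------

def daily_profile(series: HourlySeries) -> np.ndarray:
    """Hour-of-day means over the window (NaN for empty bins)."""
    hod = series.hour_of_day()[series.mask]
    counts = np.bincount(hod, minlength=24).astype(float)
    sums = np.bincount(hod, weights=series.values[series.mask], minlength=24)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def m10_l5(series: HourlySeries) -> tuple[float, float]:
    """Mean level over the most active 10 and least active 5 consecutive
    hours of the average 24-h profile (circular runs).  NaN when any
    hour-of-day bin has no data."""
    profile = daily_profile(series)
    if np.isnan(profile).any():
        return float("nan"), float("nan")
    ext = np.concatenate([profile, profile])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means10 = (csum[10:34] - csum[:24]) / 10.0
    means5 = (csum[5:29] - csum[:24]) / 5.0
    return float(means10.max()), float(means5.min())


def relative_amplitude(m10: float, l5: float) -> float:
    """(M10 - L5) / (M10 + L5), in [0, 1] for nonnegative inputs."""
    if np.isnan(m10) or np.isnan(l5):
        return float("nan")
    denom = m10 + l5
    if denom == 0:
        return float("nan")
    return float((m10 - l5) / denom)


def template_deviation(
    series: HourlySeries, min_day_coverage: float = MIN_COVERAGE
) -> np.ndarray:
    """Deviation of each day from the window's 24-h template.

    The template is the hour-of-day mean profile.  A day's deviation is
    the mean absolute difference between its observed hourly values and
    the template.  Returns six numbers: mean/median/SD of the per-day
    deviations, then the last day's deviation repeated three times (the
    single previous-day deviation has no spread of its own).

    Days with coverage below ``min_day_coverage`` are skipped; fewer
    than 2 usable days yields all-NaN.
    """
    out = np.full(6, np.nan)
    n = len(series)
    n_days = n // 24
    if n_days < 2:
        return out
    profile = daily_profile(series)
    hod = series.hour_of_day()
    span = n_days * 24
    V = series.values[:span].reshape(n_days, 24)
    T = profile[hod[:span].reshape(n_days, 24)]
    M = series.mask[:span].reshape(n_days, 24) & ~np.isnan(T)
    counts = M.sum(axis=1)
    with np.errstate(invalid="ignore"):
        day_dev = np.where(
            counts > 0,
            (np.abs(np.nan_to_num(V - T)) * M).sum(axis=1) / np.maximum(counts, 1),
            np.nan,
        )
    usable = counts >= min_day_coverage * 24
    deviations = day_dev[usable]
    if len(deviations) < 2:
        return out
    dev = np.asarray(deviations)
    out[0] = dev.mean()
    out[1] = np.median(dev)
    out[2] = dev.std()
    out[3] = out[4] = out[5] = dev[-1]
    return out


# ---------------------------------------------------------------------------
# interday stability / intraday variability
# ---------------------------------------------------------------------------

def interday_stability(series: HourlySeries) -> float:
    """Ratio of hour-of-day-profile variance to total variance:
    ``n * sum_h (xbar_h - xbar)^2 / (q * sum_i (x_i - xbar)^2)`` with
    ``q`` hour-of-day bins.  1 for an exactly day-periodic series; NaN
    for constant or under-covered series."""
    if series.coverage() < MIN_COVERAGE or len(series) < 48:
        return float("nan")
    x = series.values[series.mask]
    n = x.size
    xbar = x.mean()
    total = ((x - xbar) ** 2).sum()
    if total == 0:
        return float("nan")
    profile = daily_profile(series)
    hourly_means = profile[~np.isnan(profile)]
    q = hourly_means.size
    return float(n * ((hourly_means - xbar) ** 2).sum() / (q * total))


def intraday_variability(series: HourlySeries) -> float:
    """Normalized mean square of successive hourly differences:
    ``n * sum (x_i - x_{i-1})^2 / (n_pairs * sum (x_i - xbar)^2)``.
    Differences are taken only between consecutively observed hours.
    Exactly 4 for an alternating series, ~2 for white noise; NaN for
    constant or under-covered series."""
    if series.coverage() < MIN_COVERAGE or len(series) < 3:
        return float("nan")
    x = series.values[series.mask]
    n = x.size
    xbar = x.mean()
    total = ((x - xbar) ** 2).sum()
    if total == 0:
        return float("nan")
    consecutive = np.diff(np.flatnonzero(series.mask)) == 1
    diffs = np.diff(series.values[series.mask])[consecutive]
    if diffs.size == 0:
        return float("nan")
    return float(n * (diffs**2).sum() / (diffs.size * total))
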