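"""Synthetic cohort generator with planted, recoverable structure.

Produces smartphone-sensing-like streams (continuous ambient signals,
Poisson event streams) whose hourly intensity is a sum of sinusoids with
planted ultradian / circadian / infradian periods, plus momentary
self-report scores generated from a sparse linear map of the true
(noise-free) rhythm features.  Patients belong to planted subtypes that
share a common sparse weight support, so feature selection, the
multi-task-over-patients ordering, and subtype clustering all have
ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhythm_mtl.features import (
    SYMPTOMS,
    WINDOWS_DAYS,
    FeatureName,
    canonical_feature_names,
)
from rhythm_mtl.hourly import HourlySeries, SensorStream

__all__ = [
    "MODALITY_KINDS",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_event_stream",
    "write_cohort",
]

#: Default stream kind per known modality name.
MODALITY_KINDS = {
    "acceleration": "continuous",
    "light": "continuous",
    "sound": "continuous",
    "location": "continuous",  # daily-distance proxy, hourly grid
    "screen": "event",
    "sms": "event",
    "call": "event",
    "conversation": "event",
    "app_usage": "event",
}

#: Offset added to the weighted feature score before discretization, the
#: midpoint of the 0-3 response scale.
SCORE_OFFSET = 1.5


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`.

    ``subtype_spec`` maps cohort fractions to a dominant modality; the
    planted weight support of each subtype concentrates on features of
    that modality.
    """

    n_patients: int = 8
    n_days: int = 40
    ema_cadence_days: tuple[int, int] = (2, 3)
    modalities: tuple[str, ...] = ("light", "sound", "acceleration", "screen", "sms", "call")
    n_true_features: int = 8
    noise_sd: float = 0.25
    subtype_spec: tuple[tuple[float, str], ...] = ((0.5, "light"), (0.5, "screen"))
    dominant_fraction: float = 0.75
    seed: int = 0
    missing_fraction: float = 0.05
    sensor_noise_sd: float = 0.5
    weight_scale: float = 0.9
    ultradian_period_h: float = 16.0
    infradian_period_h: float = 64.0
    start: str = "2023-01-02"
    windows: tuple[int, ...] = WINDOWS_DAYS

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.n_days < 16:
            raise ValueError("need n_days >= 16 so a 14-day window fits a report")
        fractions = [f for f, _ in self.subtype_spec]
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1")
        for _, modality in self.subtype_spec:
            if modality not in self.modalities:
                raise ValueError(f"subtype modality {modality!r} not in modalities")
        for modality in self.modalities:
            if modality not in MODALITY_KINDS:
                raise ValueError(f"unknown modality {modality!r}")
        longest_h = max(self.windows) * 24
        for p in (self.ultradian_period_h, 24.0, self.infradian_period_h):
            if p > longest_h:
                raise ValueError(
                    f"planted period {p} h exceeds the longest analysis window"
                )
        if not 0 < self.ultradian_period_h < 20:
            raise ValueError("ultradian period must be in (0, 20) h")
        if self.infradian_period_h <= 30:
            raise ValueError("infradian period must exceed 30 h")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort.

    true_weights
        patient -> DataFrame (canonical features x symptoms); nonzero
        rows are identical within a subtype (joint sparsity).
    subtype_labels
        patient -> subtype index.
    rhythm_params
        patient -> modality -> generating-signal parameters.
    true_features
        patient -> noise-free feature matrix (rows = report dates).
    """

    true_weights: dict[str, pd.DataFrame]
    subtype_labels: dict[str, int]
    rhythm_params: dict[str, dict[str, dict]]
    true_features: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    streams: dict[str, dict[str, SensorStream]]
    ema: dict[str, pd.DataFrame]
    ground_truth: GroundTruth

    @property
    def patients(self) -> list[str]:
        return list(self.streams.keys())


# ---------------------------------------------------------------------------
# signal construction
# ---------------------------------------------------------------------------

def _draw_rhythm_params(rng: np.random.Generator, cfg: CohortConfig, kind: str) -> dict:
    """Per-(patient, modality) generating-signal parameters: a base level
    with slow drift plus three sinusoid components (one per periodicity
    class), each with slow amplitude modulation so windowed features
    vary across report dates."""
    base = rng.uniform(3.0, 6.0) if kind == "continuous" else rng.uniform(2.0, 5.0)
    components = []
    for period, amp_lo, amp_hi in (
        (24.0, 0.45, 0.75),
        (cfg.ultradian_period_h, 0.2, 0.4),
        (cfg.infradian_period_h, 0.25, 0.45),
    ):
        components.append(
            {
                "period_h": period,
                "amplitude": base * rng.uniform(amp_lo, amp_hi),
                "phase": rng.uniform(0, 2 * np.pi),
                "mod_period_h": rng.uniform(250.0, 600.0),
                "mod_depth": rng.uniform(0.3, 0.6),
                "mod_phase": rng.uniform(0, 2 * np.pi),
            }
        )
    return {
        "base": base,
        "base_mod_period_h": rng.uniform(300.0, 700.0),
        "base_mod_depth": rng.uniform(0.05, 0.15),
        "base_mod_phase": rng.uniform(0, 2 * np.pi),
        "components": components,
    }


def evaluate_signal(params: dict, t_hours: np.ndarray) -> np.ndarray:
    """Noise-free generating signal at times ``t_hours`` (hours from the
    cohort start), clipped to be nonnegative."""
    t = np.asarray(t_hours, dtype=float)
    out = params["base"] * (
        1.0
        + params["base_mod_depth"]
        * np.sin(2 * np.pi * t / params["base_mod_period_h"] + params["base_mod_phase"])
    )
    for c in params["components"]:
        amp = c["amplitude"] * (
            1.0
            + c["mod_depth"] * np.sin(2 * np.pi * t / c["mod_period_h"] + c["mod_phase"])
        )
        out = out + amp * np.cos(2 * np.pi * t / c["period_h"] + c["phase"])
    return np.clip(out, 0.0, None)


def generate_event_stream(
    rate_profile: HourlySeries, seed: int | np.random.Generator
) -> SensorStream:
    """Inhomogeneous Poisson event stream from an hourly rate profile.

    Counts per hour are Poisson with the profile's rate; timestamps are
    uniform within their hour.  Masked hours produce no events.
    """
    if np.any(rate_profile.values < 0):
        raise ValueError("rate profile must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.where(rate_profile.mask, rate_profile.values, 0.0)
    counts = rng.poisson(rates)
    hours = np.repeat(np.arange(len(rates)), counts)
    # whole seconds so CSV round-trips are lossless
    offsets = rng.integers(0, 3600, size=hours.size)
    ts = rate_profile.start + pd.to_timedelta(hours * 3600 + offsets, unit="s")
    return SensorStream(modality="", kind="event", timestamps=pd.DatetimeIndex(ts).sort_values())


def _masked_hours(rng: np.random.Generator, n_hours: int, fraction: float) -> np.ndarray:
    """Boolean mask (True = dropped) of random 1-4 h blocks covering
    roughly ``fraction`` of the span."""
    dropped = np.zeros(n_hours, dtype=bool)
    target = int(round(fraction * n_hours))
    guard = 0
    while dropped.sum() < target and guard < 10 * n_hours:
        start = int(rng.integers(0, n_hours))
        length = int(rng.integers(1, 5))
        dropped[start : start + length] = True
        guard += 1
    return dropped


# ---------------------------------------------------------------------------
# weights / subtypes
# ---------------------------------------------------------------------------

def _support_pool(modality: str, cfg: CohortConfig) -> list[str]:
    """Candidate support features for one modality: metrics that are
    well-defined on noise-free signals, over mid-length windows."""
    metrics = [
        "amplitude",
        "M10",
        "22-hour_PSD",
        f"{cfg.ultradian_period_h:g}-hour_PSD",
        f"{cfg.infradian_period_h:g}-hour_PSD",
        "mean_deviation",
    ]
    pool = []
    for w in (4, 8, 12):
        if w not in cfg.windows:
            continue
        for metric in metrics:
            pool.append(str(FeatureName(modality, metric, w)))
    return pool


def _subtype_templates(
    rng: np.random.Generator, cfg: CohortConfig, columns: list[str]
) -> list[pd.DataFrame]:
    """One weight template (features x symptoms) per subtype; support is
    concentrated on the subtype's dominant modality."""
    templates = []
    dominants = {m for _, m in cfg.subtype_spec}
    for _, dominant in cfg.subtype_spec:
        # keep the shared tail off every subtype's signature modality
        others = [m for m in cfg.modalities if m not in dominants]
        if not others:
            others = [m for m in cfg.modalities if m != dominant]
        secondary = others[0] if others else dominant
        n_dom = max(1, int(np.ceil(cfg.dominant_fraction * cfg.n_true_features)))
        n_sec = cfg.n_true_features - n_dom
        pool_dom = _support_pool(dominant, cfg)
        pool_sec = _support_pool(secondary, cfg)
        support = list(rng.choice(pool_dom, size=min(n_dom, len(pool_dom)), replace=False))
        if n_sec > 0:
            support += list(rng.choice(pool_sec, size=min(n_sec, len(pool_sec)), replace=False))
        W = pd.DataFrame(0.0, index=columns, columns=list(SYMPTOMS))
        for s in SYMPTOMS:
            w = rng.uniform(0.5, 1.0, size=len(support)) * rng.choice([-1.0, 1.0], size=len(support))
            w[0] = abs(w[0])  # keep one stable positive anchor per symptom
            w *= cfg.weight_scale / np.linalg.norm(w)
            W.loc[support, s] = w
        templates.append(W)
    return templates


def _true_feature_frame(
    clean: dict[str, HourlySeries], dates: pd.DatetimeIndex, needed: list[str]
) -> pd.DataFrame:
    """Noise-free feature values for the named features only.

    Computes exactly what :func:`rhythm_mtl.features.extract_features`
    would for those columns (same windowing and band edges), skipping
    the rest of the canonical space for speed.
    """
    from rhythm_mtl import metrics as rm
    from rhythm_mtl.features import _psd_periods_for_window, parse_feature_name

    parsed = [parse_feature_name(n) for n in needed]
    groups: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for name, fn in zip(needed, parsed):
        groups.setdefault((fn.modality, fn.window_days), []).append((name, fn.metric))

    out = pd.DataFrame(index=dates, columns=needed, dtype=float)
    for d in dates:
        anchor = pd.Timestamp(d).normalize()
        for (modality, w), metrics in groups.items():
            window = clean[modality].slice_hours(anchor - pd.Timedelta(days=w), w * 24)
            band = None
            profile_pair = None
            deviation = None
            for name, metric in metrics:
                if metric.endswith("-hour_PSD"):
                    if band is None:
                        band = rm.psd_band_power(window, _psd_periods_for_window(w))
                    out.loc[d, name] = band[float(metric[: -len("-hour_PSD")])]
                elif metric in ("M10", "L5", "amplitude"):
                    if profile_pair is None:
                        profile_pair = rm.m10_l5(window)
                    m10, l5 = profile_pair
                    value = {"M10": m10, "L5": l5}.get(metric)
                    out.loc[d, name] = value if value is not None else rm.relative_amplitude(m10, l5)
                elif metric.endswith("_deviation"):
                    if deviation is None:
                        deviation = rm.template_deviation(window)
                    idx = {
                        "mean_deviation": 0, "median_deviation": 1, "std_deviation": 2,
                        "prev_mean_deviation": 3, "prev_median_deviation": 4,
                        "prev_std_deviation": 5,
                    }[metric]
                    out.loc[d, name] = deviation[idx]
                else:
                    raise ValueError(f"unsupported true-feature metric {metric!r}")
    return out


def discretize_scores(raw: np.ndarray) -> np.ndarray:
    """Round-half-to-even then clip to the 0-3 response scale."""
    return np.clip(np.round(raw), 0, 3).astype(int)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate sensor streams, report tables, and ground truth.

    Identical configuration (including seed) produces bit-identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start)
    n_hours = cfg.n_days * 24
    hour_centers = np.arange(n_hours) + 0.5

    # subtype assignment: deterministic sizes from fractions, shuffled
    sizes = [int(round(f * cfg.n_patients)) for f, _ in cfg.subtype_spec]
    sizes[-1] = cfg.n_patients - sum(sizes[:-1])
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng.shuffle(labels)

    columns = canonical_feature_names(cfg.modalities, cfg.windows)
    templates = _subtype_templates(rng, cfg, columns)

    streams: dict[str, dict[str, SensorStream]] = {}
    ema_tables: dict[str, pd.DataFrame] = {}
    true_weights: dict[str, pd.DataFrame] = {}
    subtype_labels: dict[str, int] = {}
    rhythm_params: dict[str, dict[str, dict]] = {}
    true_features: dict[str, pd.DataFrame] = {}

    for i in range(cfg.n_patients):
        patient = f"p{i:02d}"
        subtype = int(labels[i])
        subtype_labels[patient] = subtype

        params = {m: _draw_rhythm_params(rng, cfg, MODALITY_KINDS[m]) for m in cfg.modalities}
        rhythm_params[patient] = params

        # noise-free hourly series per modality (signal / Poisson rate)
        clean = {
            m: HourlySeries(start=start, values=evaluate_signal(params[m], hour_centers))
            for m in cfg.modalities
        }

        # observed streams: sensor noise / Poisson thinning + masking
        patient_streams: dict[str, SensorStream] = {}
        for m in cfg.modalities:
            dropped = _masked_hours(rng, n_hours, cfg.missing_fraction)
            if MODALITY_KINDS[m] == "continuous":
                noisy = clean[m].values + rng.normal(0.0, cfg.sensor_noise_sd, n_hours)
                noisy = np.clip(noisy, 0.0, None)
                keep = ~dropped
                ts = start + pd.to_timedelta((np.flatnonzero(keep) + 0.5) * 3600.0, unit="s")
                patient_streams[m] = SensorStream(
                    modality=m, kind="continuous",
                    timestamps=pd.DatetimeIndex(ts), values=noisy[keep],
                )
            else:
                rate = HourlySeries(start=start, values=clean[m].values, mask=~dropped)
                stream = generate_event_stream(rate, rng)
                stream.modality = m
                patient_streams[m] = stream
        streams[patient] = patient_streams

        # report dates: every 2-3 days once the longest window fits
        lo, hi = cfg.ema_cadence_days
        day = max(cfg.windows)
        days = []
        while day < cfg.n_days:
            days.append(day)
            day += int(rng.integers(lo, hi + 1))
        dates = pd.DatetimeIndex([start + pd.Timedelta(days=d) for d in days])

        W = templates[subtype].copy()
        jitter = 1.0 + rng.uniform(-0.1, 0.1, size=W.shape)
        W = W * jitter  # preserves the subtype's common support
        true_weights[patient] = W

        # true (noise-free) features: only the union of planted supports
        # is ever weighted, so only those columns are materialized
        support_union = sorted(
            {f for t in templates for f in t.index[(t != 0).any(axis=1)]},
            key=columns.index,
        )
        F = _true_feature_frame(clean, dates, support_union)
        true_features[patient] = F

        support = W.index[(W != 0).any(axis=1)]
        Z = F[support]
        sd = Z.std(ddof=0).replace(0.0, np.nan)
        Z = ((Z - Z.mean()) / sd).fillna(0.0)
        raw = Z.to_numpy() @ W.loc[support].to_numpy()
        raw = SCORE_OFFSET + raw + rng.normal(0.0, cfg.noise_sd, raw.shape)
        scores = discretize_scores(raw)
        ema_tables[patient] = pd.DataFrame(scores, index=dates, columns=list(SYMPTOMS))

    truth = GroundTruth(
        true_weights=true_weights,
        subtype_labels=subtype_labels,
        rhythm_params=rhythm_params,
        true_features=true_features,
    )
    return Cohort(config=cfg, streams=streams, ema=ema_tables, ground_truth=truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as plain CSV/JSON files; returns the manifest path.

    Layout: one ``<patient>_<modality>.csv`` per stream with columns
    ``timestamp,value`` (ISO-8601 UTC), one ``<patient>_ema.csv`` per
    patient, ``ground_truth.json``, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {"streams": {}, "ema": {}}
    for patient, mods in cohort.streams.items():
        for modality, stream in mods.items():
            name = f"{patient}_{modality}.csv"
            values = stream.values if stream.values is not None else np.ones(len(stream))
            df = pd.DataFrame(
                {"timestamp": stream.timestamps.strftime("%Y-%m-%dT%H:%M:%SZ"), "value": values}
            )
            df.to_csv(out / name, index=False)
            files["streams"][f"{patient}/{modality}"] = name
    for patient, table in cohort.ema.items():
        name = f"{patient}_ema.csv"
        df = table.copy()
        df.insert(0, "date", table.index.strftime("%Y-%m-%d"))
        df.to_csv(out / name, index=False)
        files["ema"][patient] = name

    truth = cohort.ground_truth
    gt = {
        "subtype_labels": truth.subtype_labels,
        "rhythm_params": truth.rhythm_params,
        "true_weights": {
            p: {
                feat: {s: float(W.loc[feat, s]) for s in W.columns if W.loc[feat, s] != 0}
                for feat in W.index[(W != 0).any(axis=1)]
            }
            for p, W in truth.true_weights.items()
        },
        "score_offset": SCORE_OFFSET,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))

    cfg = cohort.config.__dict__.copy()
    manifest = {
        "config": _jsonable(cfg),
        "modality_kinds": {m: MODALITY_KINDS[m] for m in cohort.config.modalities},
        "files": files,
        "ground_truth": "ground_truth.json",
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
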