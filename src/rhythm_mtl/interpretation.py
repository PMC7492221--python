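"""Weight-based interpretation: feature ranking, factor contributions,
and patient subtyping.

Every fitted weight is tagged (through its feature name) with a sensor
modality, a rhythm metric (hence a periodicity class) and a window
length.  The contribution of a factor within one of those dimensions is
the mean absolute weight over the features carrying that factor; the
positive-weight and negative-weight means are reported separately as
well.  Subtypes are clusters of patients in absolute-weight space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from rhythm_mtl.features import parse_feature_name

__all__ = [
    "FactorContribution",
    "SubtypeResult",
    "rank_features",
    "factor_contribution",
    "find_subtypes",
    "compare_subtypes",
]

DIMENSIONS = ("modality", "periodicity", "window")


@dataclass
class FactorContribution:
    dimension: str
    factor: str
    c_p: float          # mean |w| over the factor's features
    positive_mean: float  # mean of the positive weights (0 if none)
    negative_mean: float  # mean |w| of the negative weights (0 if none)
    n_features: int


@dataclass
class SubtypeResult:
    labels: pd.Series            # patient -> cluster id (0..K-1)
    chosen_k: int
    silhouettes: dict[int, float]
    centroids: np.ndarray
    flagged_k: list[int]


def _weight_series(fit_or_weights) -> pd.Series:
    if isinstance(fit_or_weights, pd.Series):
        return fit_or_weights
    W = fit_or_weights.weights
    if W.shape[1] == 1:
        return W.iloc[:, 0]
    raise ValueError("pass a single weight column (one task) for ranking")


def rank_features(fit_or_weights, n: int | None = None, tol: float = 1e-12) -> list[str]:
    """Feature names sorted by absolute weight, descending; ties broken
    lexicographically.  All-zero weight vectors give an empty list."""
    w = _weight_series(fit_or_weights)
    nz = w[w.abs() > tol]
    if nz.empty:
        return []
    order = sorted(nz.index, key=lambda f: (-abs(nz[f]), f))
    return order[:n] if n is not None else order


def _factor_of(name: str, dimension: str) -> str:
    fn = parse_feature_name(name)
    if dimension == "modality":
        return fn.modality
    if dimension == "periodicity":
        return fn.periodicity
    if dimension == "window":
        return f"{fn.window_days}-day"
    raise ValueError(f"unknown dimension {dimension!r}")


def factor_contribution(weights: pd.Series, dimension: str) -> list[FactorContribution]:
    """Mean aggregated absolute weight c_p per factor of one dimension.

    For periodicity, metrics collapse to the three rhythm classes
    before averaging.  Unparseable feature names raise.
    """
    factors: dict[str, list[float]] = {}
    for name, w in weights.items():
        factors.setdefault(_factor_of(name, dimension), []).append(float(w))
    out = []
    for factor in sorted(factors):
        vals = np.asarray(factors[factor])
        pos = vals[vals > 0]
        neg = vals[vals < 0]
        out.append(
            FactorContribution(
                dimension=dimension,
                factor=factor,
                c_p=float(np.abs(vals).mean()),
                positive_mean=float(pos.mean()) if pos.size else 0.0,
                negative_mean=float(np.abs(neg).mean()) if neg.size else 0.0,
                n_features=int(vals.size),
            )
        )
    return out


def find_subtypes(
    weight_vectors: pd.DataFrame,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    normalize: bool = True,
) -> SubtypeResult:
    """Cluster patients by their absolute model-weight vectors.

    K-Means (k-means++, 10 restarts) is run for every K in ``k_range``;
    the K maximizing the mean silhouette (Euclidean) wins.  Weight
    vectors are L2-normalized after taking absolute values when
    ``normalize`` is set.  Ks whose silhouette is undefined (identical
    points within every cluster pairing, or K >= n) are skipped; if all
    are skipped a ValueError is raised.
    """
    V = weight_vectors.abs().to_numpy(dtype=float)
    if normalize:
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        V = V / np.where(norms == 0, 1.0, norms)
    n = len(V)
    lo, hi = k_range
    if n < lo + 1:
        raise ValueError("need more patients than the smallest K")
    silhouettes: dict[int, float] = {}
    results: dict[int, KMeans] = {}
    flagged: list[int] = []
    for k in range(lo, min(hi, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(V)
        if len(np.unique(labels)) < 2:
            flagged.append(k)
            continue
        try:
            score = float(silhouette_score(V, labels, metric="euclidean"))
        except ValueError:
            flagged.append(k)
            continue
        if np.isnan(score):
            flagged.append(k)
            continue
        silhouettes[k] = score
        results[k] = km
    if not silhouettes:
        raise ValueError("silhouette undefined for every K in range")
    chosen = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    km = results[chosen]
    labels = pd.Series(km.labels_, index=weight_vectors.index, name="subtype")
    return SubtypeResult(
        labels=labels,
        chosen_k=chosen,
        silhouettes=silhouettes,
        centroids=km.cluster_centers_,
        flagged_k=flagged,
    )


def compare_subtypes(
    result: SubtypeResult,
    weight_vectors: pd.DataFrame,
    ema_means: pd.DataFrame | None = None,
    top_n: int = 10,
) -> dict[int, dict]:
    """Per-subtype summaries: top features by within-cluster mean
    weight, factor contributions per dimension, and mean report scores.

    Singleton clusters are summarized but flagged.
    """
    out: dict[int, dict] = {}
    for k in sorted(result.labels.unique()):
        members = result.labels.index[result.labels == k]
        mean_w = weight_vectors.loc[members].mean(axis=0)
        top = rank_features(mean_w, n=top_n)
        summary = {
            "n_patients": int(len(members)),
            "patients": list(members),
            "small_cluster": len(members) < 2,
            "top_features": [(f, float(mean_w[f])) for f in top],
            "factor_contributions": {
                dim: [c.__dict__ for c in factor_contribution(mean_w, dim)]
                for dim in DIMENSIONS
            },
        }
        if ema_means is not None:
            summary["mean_ema"] = ema_means.loc[members].mean(axis=0).to_dict()
        out[int(k)] = summary
    return out
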