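"""Training/evaluation protocols, RMSE tables, and paired statistics.

Seven protocols are supported, keyed A-G:

==  =======================  ==========================  ============
id  model                    granularity                 default CV
==  =======================  ==========================  ============
A   m-SVR (linear kernel)    per patient, all symptoms   fivefold
B   m-SVR (RBF kernel)       per patient, all symptoms   fivefold
C   MTL-patients (l2,1)      per symptom, all patients   semi-LOSO
D   MTL-symptoms (l2,1)      per patient, all symptoms   fivefold
E   MTL-symptoms pooled      all patients & symptoms     LOSO
F   LASSO                    per patient & symptom       fivefold
G   LASSO pooled             per symptom, all patients   LOSO
==  =======================  ==========================  ============

Every protocol also runs under a per-patient chronological 80/20 split
(train on the first 80% of each patient's reports, test on the rest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rhythm_mtl.models import fit_lasso_stl, fit_msvr, fit_mtl_l21, predict

__all__ = [
    "ALGORITHMS",
    "CVPlan",
    "make_cv_plan",
    "run_protocol",
    "rmse",
    "rmse_table",
    "summarize",
    "paired_signed_rank",
    "holm_bonferroni",
]

ALGORITHMS = {
    "A": "msvr_linear",
    "B": "msvr_rbf",
    "C": "mtl_patients",
    "D": "mtl_symptoms",
    "E": "mtl_symptoms_generalized",
    "F": "stl_personalized",
    "G": "stl_generalized",
}

_DEFAULT_SCHEME = {
    "A": "fivefold", "B": "fivefold", "C": "semi_loso", "D": "fivefold",
    "E": "loso", "F": "fivefold", "G": "loso",
}


@dataclass
class CVPlan:
    """Fold assignment per (patient, report row).

    ``folds`` maps patient -> integer fold label per row (aligned with
    that patient's feature-matrix rows).  For the chronological scheme
    fold 0 is the training block and fold 1 the test block.
    """

    scheme: str
    folds: dict[str, np.ndarray]
    seed: int
    n_folds: int = 5

    def __post_init__(self) -> None:
        for patient, f in self.folds.items():
            if len(f) == 0:
                raise ValueError(f"patient {patient} has no rows")


def make_cv_plan(
    row_counts: dict[str, int],
    scheme: str,
    seed: int = 0,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> CVPlan:
    """Build fold assignments for every patient.

    fivefold / semi_loso: random per-patient partition into ``n_folds``
    folds.  loso: a single fold per patient (index 0).  chronological:
    the last ``test_fraction`` of rows (time-ordered) form fold 1.
    """
    rng = np.random.default_rng(seed)
    folds: dict[str, np.ndarray] = {}
    for patient in sorted(row_counts):
        n = row_counts[patient]
        if scheme in ("fivefold", "semi_loso"):
            if n < n_folds:
                raise ValueError(
                    f"patient {patient} has {n} rows; needs >= {n_folds} for {scheme}"
                )
            labels = np.arange(n) % n_folds
            rng.shuffle(labels)
            folds[patient] = labels
        elif scheme == "loso":
            folds[patient] = np.zeros(n, dtype=int)
        elif scheme == "chronological":
            n_test = max(1, int(round(test_fraction * n)))
            if n_test >= n:
                raise ValueError(f"patient {patient} has too few rows to split")
            labels = np.zeros(n, dtype=int)
            labels[n - n_test :] = 1
            folds[patient] = labels
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return CVPlan(scheme=scheme, folds=folds, seed=seed, n_folds=n_folds)


# ---------------------------------------------------------------------------
# protocol execution
# ---------------------------------------------------------------------------

def _trainer(algorithm: str, params: dict):
    alpha = params.get("alpha", 0.05)
    C = params.get("C", 10.0)
    lam = params.get("lam", 1.0)
    if algorithm == "A":
        return lambda X, Y: fit_msvr(X, Y, kernel="linear", C=C, lam=lam)
    if algorithm == "B":
        return lambda X, Y: fit_msvr(X, Y, kernel="rbf", C=C, lam=lam)
    if algorithm in ("D", "E"):
        return lambda X, Y: fit_mtl_l21(X, Y, alpha=alpha, layout="symptoms")
    raise ValueError(algorithm)


def _splits(plan: CVPlan, patient: str):
    """(train_mask, test_mask) per fold for one patient."""
    labels = plan.folds[patient]
    if plan.scheme == "chronological":
        yield labels == 0, labels == 1
    else:
        for f in np.unique(labels):
            yield labels != f, labels == f


def run_protocol(
    algorithm: str,
    data: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    plan: CVPlan,
    params: dict | None = None,
) -> pd.DataFrame:
    """Out-of-fold predictions for one protocol.

    Parameters
    ----------
    algorithm : {"A", ..., "G"}
    data : dict
        patient -> (X_u, Y_u); all X_u share the canonical columns and
        Y_u carry the symptom columns.
    plan : CVPlan
        Scheme must suit the algorithm (personalized models: fivefold or
        chronological; MTL-patients: semi_loso or chronological; pooled
        models: loso or chronological).

    Returns
    -------
    DataFrame with columns patient, symptom, row, y_true, y_pred; one
    prediction per (report row, symptom).
    """
    params = dict(params or {})
    records: list[tuple] = []
    patients = list(data.keys())
    symptoms = list(next(iter(data.values()))[1].columns)

    def emit(patient, mask, preds):
        X_u, Y_u = data[patient]
        rows = np.flatnonzero(mask)
        for s in symptoms:
            p = preds[s] if isinstance(preds, pd.DataFrame) else preds
            for r, yhat in zip(rows, np.asarray(p, dtype=float)):
                records.append((patient, s, int(r), float(Y_u[s].iloc[r]), float(yhat)))

    if algorithm in ("A", "B", "D"):
        train = _trainer(algorithm, params)
        for patient in patients:
            X_u, Y_u = data[patient]
            for tr, te in _splits(plan, patient):
                if tr.sum() < 2:
                    continue
                fit = train(X_u.loc[tr], Y_u.loc[tr])
                emit(patient, te, predict(fit, X_u.loc[te]))

    elif algorithm == "C":
        alpha = params.get("alpha", 0.05)
        for s in symptoms:
            if plan.scheme == "chronological":
                Xb = {u: data[u][0].loc[plan.folds[u] == 0] for u in patients}
                Yb = {u: data[u][1][s].loc[plan.folds[u] == 0] for u in patients}
                fit = fit_mtl_l21(Xb, Yb, alpha=alpha, layout="patients")
                for u in patients:
                    te = plan.folds[u] == 1
                    pred = predict(fit, data[u][0].loc[te], task=u)
                    _emit_single(records, data, u, s, te, pred)
            else:  # semi-LOSO: test patient's held-in folds + everyone else
                for u in patients:
                    for tr, te in _splits(plan, u):
                        if tr.sum() < 2:
                            continue
                        Xb = {v: (data[v][0] if v != u else data[u][0].loc[tr]) for v in patients}
                        Yb = {v: (data[v][1][s] if v != u else data[u][1][s].loc[tr]) for v in patients}
                        fit = fit_mtl_l21(Xb, Yb, alpha=alpha, layout="patients")
                        pred = predict(fit, data[u][0].loc[te], task=u)
                        _emit_single(records, data, u, s, te, pred)

    elif algorithm == "E":
        train = _trainer("E", params)
        for u, tr_pool, te_mask in _pooled_splits(plan, data):
            X_tr = pd.concat([data[v][0].loc[m] for v, m in tr_pool], axis=0)
            Y_tr = pd.concat([data[v][1].loc[m] for v, m in tr_pool], axis=0)
            fit = train(X_tr, Y_tr)
            emit(u, te_mask, predict(fit, data[u][0].loc[te_mask]))

    elif algorithm == "F":
        alpha = params.get("alpha", 0.05)
        for patient in patients:
            X_u, Y_u = data[patient]
            for s in symptoms:
                for tr, te in _splits(plan, patient):
                    if tr.sum() < 2:
                        continue
                    fit = fit_lasso_stl(X_u.loc[tr], Y_u[s].loc[tr], alpha=alpha)
                    pred = predict(fit, X_u.loc[te], task="y")
                    _emit_single(records, data, patient, s, te, pred)

    elif algorithm == "G":
        alpha = params.get("alpha", 0.05)
        for s in symptoms:
            for u, tr_pool, te_mask in _pooled_splits(plan, data):
                X_tr = pd.concat([data[v][0].loc[m] for v, m in tr_pool], axis=0)
                y_tr = pd.concat([data[v][1][s].loc[m] for v, m in tr_pool], axis=0)
                fit = fit_lasso_stl(X_tr, y_tr, alpha=alpha)
                pred = predict(fit, data[u][0].loc[te_mask], task="y")
                _emit_single(records, data, u, s, te_mask, pred)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    return pd.DataFrame(records, columns=["patient", "symptom", "row", "y_true", "y_pred"])


def _emit_single(records, data, patient, symptom, mask, pred):
    Y_u = data[patient][1]
    rows = np.flatnonzero(mask)
    for r, yhat in zip(rows, np.asarray(pred, dtype=float)):
        records.append((patient, symptom, int(r), float(Y_u[symptom].iloc[r]), float(yhat)))


def _pooled_splits(plan: CVPlan, data):
    """Yield (test_patient, training pool, test mask) for pooled models.

    LOSO: train on all other patients.  Chronological: train on every
    patient's first block, test each patient's last block.
    """
    patients = list(data.keys())
    if plan.scheme == "loso":
        for u in patients:
            pool = [(v, np.ones(len(data[v][0]), dtype=bool)) for v in patients if v != u]
            yield u, pool, np.ones(len(data[u][0]), dtype=bool)
    elif plan.scheme == "chronological":
        pool = [(v, plan.folds[v] == 0) for v in patients]
        for u in patients:
            yield u, pool, plan.folds[u] == 1
    else:
        raise ValueError(f"pooled models need loso or chronological, got {plan.scheme!r}")


# ---------------------------------------------------------------------------
# metrics and tests
# ---------------------------------------------------------------------------

def rmse(pred, truth) -> float:
    """Root-mean-square error; raises on empty or mismatched input."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predictions and truth must be nonempty and aligned")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def rmse_fraction_of_scale(value: float, scale: float = 3.0) -> float:
    """RMSE as a percentage of the 0-3 response scale."""
    return 100.0 * value / scale


def rmse_table(predictions: pd.DataFrame, algorithm: str, scheme: str) -> pd.DataFrame:
    """Long-format RMSE per (patient, symptom) from a prediction frame."""
    rows = []
    for (patient, symptom), grp in predictions.groupby(["patient", "symptom"], sort=True):
        rows.append(
            {
                "algorithm": algorithm,
                "patient": patient,
                "symptom": symptom,
                "scheme": scheme,
                "rmse": rmse(grp["y_pred"], grp["y_true"]),
            }
        )
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Mean/median RMSE per algorithm with a percentile bootstrap CI."""
    rng = np.random.default_rng(seed)
    rows = []
    for algorithm, grp in table.groupby("algorithm"):
        vals = grp["rmse"].to_numpy()
        boots = np.array(
            [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
        )
        rows.append(
            {
                "algorithm": algorithm,
                "mean_rmse": vals.mean(),
                "median_rmse": float(np.median(vals)),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "n_cells": len(vals),
            }
        )
    return pd.DataFrame(rows)


def paired_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped.  Exact null for n <= 25 pairs,
    normal approximation with continuity correction otherwise.  The
    statistic is ``W+ - W-`` (antisymmetric under swapping a and b).

    Returns (statistic, p); p is NaN when all pairs are tied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = stats.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    w_minus = float(ranks[diff < 0].sum())
    statistic = w_plus - w_minus
    if n <= 25:
        res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            diff, zero_method="wilcox", alternative="two-sided",
            method="approx", correction=True,
        )
    return statistic, float(res.pvalue)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
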