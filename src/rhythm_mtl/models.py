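"""Model families: single-task LASSO, l2,1-regularized multi-task
regression (shared-support across symptoms or across patients), and
multi-output least-squares SVR with a mean regressor plus per-task
adjustments.

Conventions shared by the linear fits
-------------------------------------
* Features are z-scored on the training data (zero-variance columns get
  unit scale and necessarily zero weight); labels are centered per task.
  Reported weights live in the standardized feature space, which makes
  them comparable across patients for the interpretation layer.
* Objectives use the averaged-squared-error scale:

  - STL:            (1/2n)||y - Xw||^2 + alpha*|w|_1
  - MTL-symptoms:   (1/2n)||Y - XW||_F^2 + alpha*||W||_{2,1}
  - MTL-patients:   sum_u c_u/2 ||y_u - X_u w_u||^2 + alpha*||W||_{2,1}
    with c_u = 1/e_u by default (switchable to the unnormalized sum).

  ||W||_{2,1} = sum over feature rows of the Euclidean norm across
  tasks, which drives whole rows to zero jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

__all__ = [
    "ModelFit",
    "MsvrFit",
    "fit_lasso_stl",
    "fit_mtl_l21",
    "l21_norm",
    "l21_objective",
    "fit_msvr",
    "predict",
    "select_alpha",
]


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted linear model (one or many tasks).

    ``weights`` is (features x tasks) in standardized feature space;
    ``predict`` undoes the standardization internally.
    """

    weights: pd.DataFrame
    intercepts: pd.Series
    alpha: float
    layout: str  # "stl" | "symptoms" | "patients"
    feature_mean: pd.Series
    feature_scale: pd.Series
    n_iter: int = 0
    objective: float = float("nan")
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    def nonzero_rows(self, tol: float = 1e-8) -> pd.Index:
        norms = np.sqrt((self.weights**2).sum(axis=1))
        return self.weights.index[norms > tol]

    def to_dict(self) -> dict:
        return {
            "layout": self.layout,
            "alpha": self.alpha,
            "weights": {t: self.weights[t].to_dict() for t in self.weights.columns},
            "intercepts": self.intercepts.to_dict(),
            "n_iter": self.n_iter,
            "objective": self.objective,
            "converged": self.converged,
        }


@dataclass
class MsvrFit:
    """Dual-form multi-output least-squares SVR fit.

    The regressor for task t is ``w0 + v_t``; in the dual this becomes
    ``f_t(x) = sum_i (a_sum_i + (T/lam) a_{it}) K(x_i, x) + b_t``.
    """

    X_train: np.ndarray
    A: np.ndarray  # (n_samples, n_tasks) dual variables
    b: np.ndarray
    kernel: str
    gamma: float
    C: float
    lam: float
    tasks: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    jittered: bool = False


# ---------------------------------------------------------------------------
# standardization helpers
# ---------------------------------------------------------------------------

def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    mean = X.mean()
    scale = X.std(ddof=0).replace(0.0, 1.0)
    Z = ((X - mean) / scale).to_numpy()
    return Z, mean, scale


# ---------------------------------------------------------------------------
# LASSO (single task)
# ---------------------------------------------------------------------------

def fit_lasso_stl(X: pd.DataFrame, y: pd.Series | np.ndarray, alpha: float) -> ModelFit:
    """LASSO fit of one task: min (1/2n)||y - Xw||^2 + alpha*|w|_1.

    ``alpha == 0`` falls back to ordinary least squares.  Pooled
    (generalized) fits are obtained by row-concatenating patients before
    the call.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("X and y must align with at least 2 rows")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    Z, mean, scale = _standardize(X)
    y_mean = y.mean()
    yc = y - y_mean
    if alpha == 0:
        w, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        n_iter, obj = 0, float(0.5 * np.mean((yc - Z @ w) ** 2))
    else:
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000, tol=1e-8)
        model.fit(Z, yc)
        w = model.coef_
        n_iter = int(model.n_iter_)
        obj = float(0.5 * np.mean((yc - Z @ w) ** 2) + alpha * np.abs(w).sum())
    weights = pd.DataFrame({"y": w}, index=X.columns)
    intercepts = pd.Series({"y": y_mean})
    return ModelFit(
        weights=weights, intercepts=intercepts, alpha=alpha, layout="stl",
        feature_mean=mean, feature_scale=scale, n_iter=n_iter, objective=obj,
    )


# ---------------------------------------------------------------------------
# l2,1 multi-task solver
# ---------------------------------------------------------------------------

def l21_norm(W: np.ndarray) -> float:
    return float(np.sqrt((W**2).sum(axis=1)).sum())


def _row_shrink(W: np.ndarray, thresh: float) -> np.ndarray:
    """Group soft-threshold every feature row of W by ``thresh``."""
    norms = np.sqrt((W**2).sum(axis=1, keepdims=True))
    factor = np.maximum(0.0, 1.0 - thresh / np.maximum(norms, 1e-300))
    return W * factor


def _smooth_loss_grad(W, Xs, Ys, coefs, col_slices):
    """Smooth part sum_u c_u/2 ||Y_u - X_u W_u||^2 and its gradient.

    ``col_slices[u]`` selects the columns of W belonging to block u (all
    columns for the shared-design layout)."""
    loss = 0.0
    grad = np.zeros_like(W)
    for X, Y, c, sl in zip(Xs, Ys, coefs, col_slices):
        R = X @ W[:, sl] - Y
        loss += 0.5 * c * float((R**2).sum())
        grad[:, sl] += c * (X.T @ R)
    return loss, grad


def l21_objective(W, Xs, Ys, coefs, col_slices, alpha) -> float:
    loss, _ = _smooth_loss_grad(W, Xs, Ys, coefs, col_slices)
    return loss + alpha * l21_norm(W)


def _ista_l21(Xs, Ys, coefs, col_slices, d, k, alpha, max_iter, tol):
    """Monotone proximal-gradient (ISTA with backtracking) minimizer."""
    W = np.zeros((d, k))
    loss, grad = _smooth_loss_grad(W, Xs, Ys, coefs, col_slices)
    obj = loss + alpha * l21_norm(W)
    history = [obj]
    L = 1.0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        while True:
            W_new = _row_shrink(W - grad / L, alpha / L)
            D = W_new - W
            loss_new, grad_new = _smooth_loss_grad(W_new, Xs, Ys, coefs, col_slices)
            quad = loss + float((grad * D).sum()) + 0.5 * L * float((D**2).sum())
            if loss_new <= quad + 1e-12 * max(1.0, abs(loss)):
                break
            L *= 2.0
        obj_new = loss_new + alpha * l21_norm(W_new)
        rel = abs(obj - obj_new) / max(1.0, abs(obj))
        W, loss, grad, obj = W_new, loss_new, grad_new, obj_new
        history.append(obj)
        if rel < tol:
            converged = True
            break
        L = max(L * 0.9, 1e-10)  # allow the step size to grow back
    return W, obj, n_iter, converged, history


def fit_mtl_l21(
    X_blocks,
    Y_blocks,
    alpha: float,
    layout: str,
    normalize_tasks: bool = True,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> ModelFit:
    """Multi-task fit with a row-wise group-sparsity (l2,1) penalty.

    Parameters
    ----------
    X_blocks, Y_blocks
        ``layout="symptoms"``: a single DataFrame ``X`` and a DataFrame
        ``Y`` with one column per symptom (shared design).
        ``layout="patients"``: dicts (or aligned lists) of per-patient
        ``X_u`` / ``y_u`` sharing the same feature columns; the fitted
        ``W`` has one column per patient and the penalty couples their
        supports.
    alpha
        Regularization strength; ``alpha == 0`` reduces to exact
        per-task least squares.
    normalize_tasks
        Patients layout only: weight each block's loss by 1/e_u so
        patients with more reports do not dominate.
    """
    if layout == "symptoms":
        X = X_blocks
        Y = Y_blocks
        columns = X.columns
        tasks = list(Y.columns)
        Z, mean, scale = _standardize(X)
        Ymat = np.asarray(Y, dtype=float)
        y_means = Ymat.mean(axis=0)
        Xs = [Z]
        Ys = [Ymat - y_means]
        coefs = [1.0 / len(X)]
        col_slices = [slice(0, len(tasks))]
        scaler_mean, scaler_scale = mean, scale
    elif layout == "patients":
        if isinstance(X_blocks, dict):
            tasks = list(X_blocks.keys())
            X_list = [X_blocks[t] for t in tasks]
            y_list = [np.asarray(Y_blocks[t], dtype=float) for t in tasks]
        else:
            tasks = [f"task{i}" for i in range(len(X_blocks))]
            X_list = list(X_blocks)
            y_list = [np.asarray(y, dtype=float) for y in Y_blocks]
        columns = X_list[0].columns
        for X in X_list[1:]:
            if not X.columns.equals(columns):
                raise ValueError("per-patient blocks must share the same columns")
        Xs, Ys, coefs, col_slices = [], [], [], []
        y_means = []
        means, scales = [], []
        for j, (X, y) in enumerate(zip(X_list, y_list)):
            Z, mean, scale = _standardize(X)
            ym = y.mean()
            Xs.append(Z)
            Ys.append((y - ym)[:, None])
            coefs.append(1.0 / len(y) if normalize_tasks else 1.0)
            col_slices.append(slice(j, j + 1))
            y_means.append(ym)
            means.append(mean)
            scales.append(scale)
        y_means = np.asarray(y_means)
        # per-task scalers: stored as (features x tasks) frames
        scaler_mean = pd.concat(means, axis=1, keys=tasks)
        scaler_scale = pd.concat(scales, axis=1, keys=tasks)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    d = len(columns)
    k = len(tasks)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        W = np.zeros((d, k))
        for X, Y, sl in zip(Xs, Ys, col_slices):
            sol, *_ = np.linalg.lstsq(X, Y, rcond=None)
            W[:, sl] = sol
        obj = l21_objective(W, Xs, Ys, coefs, col_slices, 0.0)
        n_iter, converged, history = 0, True, [obj]
    else:
        W, obj, n_iter, converged, history = _ista_l21(
            Xs, Ys, coefs, col_slices, d, k, alpha, max_iter, tol
        )

    weights = pd.DataFrame(W, index=columns, columns=tasks)
    intercepts = pd.Series(np.asarray(y_means).ravel(), index=tasks)
    return ModelFit(
        weights=weights, intercepts=intercepts, alpha=alpha, layout=layout,
        feature_mean=scaler_mean, feature_scale=scaler_scale,
        n_iter=n_iter, objective=obj, converged=converged,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# multi-output least-squares SVR
# ---------------------------------------------------------------------------

def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, gamma: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        sq = (A**2).sum(axis=1)[:, None] + (B**2).sum(axis=1)[None, :] - 2 * A @ B.T
        return np.exp(-gamma * np.maximum(sq, 0.0))
    raise ValueError(f"unknown kernel {kernel!r}")


def median_heuristic_gamma(X: np.ndarray, max_points: int = 500) -> float:
    """RBF gamma = 1/(2 sigma^2) with sigma the median pairwise distance."""
    n = len(X)
    if n > max_points:
        idx = np.linspace(0, n - 1, max_points).astype(int)
        X = X[idx]
    sq = (X**2).sum(axis=1)[:, None] + (X**2).sum(axis=1)[None, :] - 2 * X @ X.T
    dists = np.sqrt(np.maximum(sq[np.triu_indices(len(X), 1)], 0.0))
    med = np.median(dists[dists > 0]) if np.any(dists > 0) else 1.0
    return float(1.0 / (2 * med**2))


def fit_msvr(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    kernel: str = "rbf",
    C: float = 10.0,
    lam: float = 1.0,
    gamma: float | None = None,
) -> MsvrFit:
    """Multi-output least-squares SVR.

    Task regressors decompose as a mean regressor plus per-task
    adjustments, ``w_t = w0 + v_t``, with penalties ``||w0||^2/2 +
    (lam/2T) sum_t ||v_t||^2`` and equality-constrained squared errors
    weighted by ``C``.  Solved as one linear system in the dual
    variables; deterministic.  A singular system is re-solved with a
    1e-10 ridge and flagged.
    """
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if C <= 0:
        raise ValueError("C must be > 0")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    tasks = list(Y.columns)
    T = len(tasks)
    Z, mean, scale = _standardize(X)
    Ymat = np.asarray(Y, dtype=float)
    n = len(Z)
    if gamma is None:
        gamma = median_heuristic_gamma(Z) if kernel == "rbf" else 0.0
    K = _kernel_matrix(Z, Z, kernel, gamma)
    if lam == 0:
        # v_t unpenalized: tasks decouple into independent LS-SVRs
        task_K = K
        ratio = 1.0
    else:
        task_K = K
        ratio = T / lam

    size = n * T + T
    M = np.zeros((size, size))
    rhs = np.zeros(size)
    for t in range(T):
        rt = slice(t * n, (t + 1) * n)
        if lam > 0:
            for s in range(T):
                M[rt, s * n : (s + 1) * n] += K
        M[rt, rt] += ratio * task_K + np.eye(n) / C
        M[rt, n * T + t] = 1.0
        M[n * T + t, rt] = 1.0
        rhs[rt] = Ymat[:, t]
    jittered = False
    try:
        sol = np.linalg.solve(M, rhs)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        jittered = True
        sol = np.linalg.solve(M + 1e-10 * np.eye(size), rhs)
    A = sol[: n * T].reshape(T, n).T
    b = sol[n * T :]
    return MsvrFit(
        X_train=Z, A=A, b=b, kernel=kernel, gamma=gamma, C=C, lam=lam,
        tasks=tasks, feature_mean=mean.to_numpy(), feature_scale=scale.to_numpy(),
        jittered=jittered,
    )


def _msvr_predict(fit: MsvrFit, X: pd.DataFrame) -> pd.DataFrame:
    Z = (np.asarray(X, dtype=float) - fit.feature_mean) / fit.feature_scale
    Kt = _kernel_matrix(Z, fit.X_train, fit.kernel, fit.gamma)
    T = len(fit.tasks)
    if fit.lam == 0:
        coeff = fit.A
    else:
        coeff = fit.A.sum(axis=1, keepdims=True) + (T / fit.lam) * fit.A
    preds = Kt @ coeff + fit.b[None, :]
    return pd.DataFrame(preds, index=X.index, columns=fit.tasks)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(
    fit: ModelFit | MsvrFit,
    X: pd.DataFrame,
    task: str | None = None,
    clip: bool = False,
) -> pd.DataFrame | pd.Series:
    """Predicted scores for every task (or one ``task``).

    Predictions are raw inner products plus intercepts; they are not
    restricted to the 0-3 response range unless ``clip=True``.
    """
    if isinstance(fit, MsvrFit):
        out = _msvr_predict(fit, X)
    elif fit.layout in ("stl", "symptoms"):
        if not X.columns.equals(fit.weights.index):
            raise ValueError("feature columns do not match the fit")
        Z = (X - fit.feature_mean) / fit.feature_scale
        out = pd.DataFrame(
            Z.to_numpy() @ fit.weights.to_numpy() + fit.intercepts.to_numpy()[None, :],
            index=X.index, columns=fit.weights.columns,
        )
    else:  # patients layout: per-task scalers
        if task is None:
            raise ValueError("patients layout requires a task (patient id)")
        if not X.columns.equals(fit.weights.index):
            raise ValueError("feature columns do not match the fit")
        mean = fit.feature_mean[task]
        scale = fit.feature_scale[task]
        Z = (X - mean) / scale
        pred = Z.to_numpy() @ fit.weights[task].to_numpy() + fit.intercepts[task]
        out = pd.Series(pred, index=X.index, name=task)
        if clip:
            out = out.clip(0, 3)
        return out
    if task is not None:
        out = out[task]
    if clip:
        out = out.clip(0, 3)
    return out


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

def select_alpha(trainer, X, Y, grid, n_folds: int = 3, seed: int = 0) -> float:
    """Inner k-fold CV over a regularization grid on the training split.

    ``trainer(X_train, Y_train, alpha)`` must return an object usable by
    :func:`predict`.  Picks the grid value with the lowest mean
    validation RMSE; ties go to the larger (sparser) value.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    if len(grid) == 1:
        return grid[0]
    rng = np.random.default_rng(seed)
    n = len(X)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    scores = []
    for alpha in grid:
        errs = []
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            if mask.sum() < 2 or len(f) == 0:
                continue
            fit = trainer(X.iloc[mask], _take(Y, mask), alpha)
            pred = np.asarray(predict(fit, X.iloc[~mask]), dtype=float)
            truth = np.asarray(_take(Y, ~mask), dtype=float)
            if pred.size != truth.size:
                raise ValueError("prediction/label size mismatch in CV")
            pred = pred.reshape(truth.shape)
            errs.append(float(np.sqrt(np.mean((pred - truth) ** 2))))
        scores.append(np.mean(errs))
    scores = np.asarray(scores)
    best = scores.min()
    candidates = [a for a, s in zip(grid, scores) if s <= best + 1e-12]
    return max(candidates)


def _take(Y, mask):
    if isinstance(Y, (pd.DataFrame, pd.Series)):
        return Y.iloc[mask] if mask.dtype == bool else Y.iloc[mask]
    return np.asarray(Y)[mask]
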