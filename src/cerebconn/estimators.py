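"""Connectivity weight estimation: winner-take-all, Lasso, and Ridge.

All three models are multivariate linear encoding models Y = XW + E mapping
T x Q cortical fitted time series onto T x P cerebellar voxel series; they
differ only in the constraint placed on each voxel's weight column:

* winner-take-all (WTA): exactly one non-zero weight — the parcel whose time
  series correlates best with the voxel;
* Lasso: argmin ||Y - XW||^2 + lambda * ||W||_1 (sparse support);
* Ridge: argmin ||Y - XW||^2 + lambda * ||W||^2 (dense, shrunk weights).

The penalized objectives are exactly as written, with no 1/2 or 1/n
prefactor; lambda is always passed on the natural-log scale.  The Lasso
solver is coordinate descent (scikit-learn's, wrapped so the solution
minimizes the objective above: sklearn's alpha equals lambda / (2T)).

Estimators follow the scikit-learn protocol (``fit(X, Y)``, ``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection; the module-level ``fit_*`` functions
are thin wrappers that consume crossed session pairs and return a
``ConnectivityWeights`` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso as _SkLasso
from sklearn.utils.validation import check_is_fitted

from ._utils import pearson_columns
from .reconstruction import CrossedPair

__all__ = [
    "ConnectivityWeights",
    "LambdaGrid",
    "WTAConnectivity",
    "RidgeConnectivity",
    "LassoConnectivity",
    "fit_wta",
    "fit_ridge",
    "fit_lasso",
    "tune_lambda",
    "group_average_weights",
    "default_grid",
]


def default_grid() -> np.ndarray:
    """Default log-lambda grid: 17 integer points from -8 to 8."""
    return np.arange(-8.0, 9.0)


@dataclass
class ConnectivityWeights:
    """A fitted Q x P connectivity weight matrix with estimator metadata."""

    W: np.ndarray
    method: str                     # 'wta' | 'lasso' | 'ridge'
    log_lambda: float | None = None
    meta: dict = field(default_factory=dict)
    degenerate_voxels: np.ndarray | None = None

    @property
    def Q(self) -> int:
        return self.W.shape[0]

    @property
    def P(self) -> int:
        return self.W.shape[1]


@dataclass
class LambdaGrid:
    """Grid-search record: candidate log-lambdas, CV accuracy, chosen value."""

    log_lambdas: np.ndarray
    cv_accuracy: np.ndarray         # mean held-out Pearson r per candidate
    chosen: float
    fold_accuracy: np.ndarray | None = None  # (n_folds, n_candidates)


def _validate_xy(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} samples but Y has {Y.shape[0]}"
        )
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("X and Y must be finite")
    return X, Y


class _BaseConnectivity(BaseEstimator, RegressorMixin):
    """Shared predict/score surface; subclasses set ``W_`` in ``fit``."""

    def predict(self, X):
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} parcels but weights expect {self.W_.shape[0]}"
            )
        return X @ self.W_

    def score(self, X, Y, sample_weight=None):
        """Mean per-voxel Pearson r between predicted and observed series."""
        r = pearson_columns(self.predict(X), np.asarray(Y, dtype=float))
        return float(np.nanmean(r))


class WTAConnectivity(_BaseConnectivity):
    """Winner-take-all model: one cortical parcel per cerebellar voxel.

    For each voxel, the winner is the parcel with the highest (signed)
    Pearson correlation with the voxel's series; ties break to the lowest
    parcel index.  The winning weight is the univariate least-squares slope
    of the voxel on the winning parcel so that predictions live on the
    response scale; all other weights are exactly zero.
    """

    def fit(self, X, Y):
        X, Y = _validate_xy(X, Y)
        T, Q = X.shape
        if T < 3:
            raise ValueError("need at least 3 timepoints")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        ssx = np.einsum("tq,tq->q", Xc, Xc)
        ssy = np.einsum("tp,tp->p", Yc, Yc)
        cross = Xc.T @ Yc                      # (Q, P) sums of products
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cross / np.sqrt(ssx[:, None] * ssy[None, :])
        corr[ssx == 0, :] = -np.inf            # degenerate parcels never win
        degenerate = ssy == 0
        corr[:, degenerate] = -np.inf
        winners = np.argmax(corr, axis=0)      # first index wins exact ties
        slopes = cross[winners, np.arange(Y.shape[1])] / ssx[winners]
        W = np.zeros((Q, Y.shape[1]))
        W[winners, np.arange(Y.shape[1])] = slopes
        W[:, degenerate] = 0.0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance voxel(s): weights set to 0",
                stacklevel=2,
            )
        self.W_ = W
        self.winners_ = winners
        self.degenerate_voxels_ = np.flatnonzero(degenerate)
        return self


class RidgeConnectivity(_BaseConnectivity):
    """Ridge model: W = (X'X + lambda I)^-1 X'Y via one shared factorization.

    ``log_lambda=-inf`` gives the unpenalized solution (minimum-norm via
    lstsq if X is rank deficient, with a warning).
    """

    def __init__(self, log_lambda: float = 0.0):
        self.log_lambda = log_lambda

    def fit(self, X, Y):
        X, Y = _validate_xy(X, Y)
        lam = float(np.exp(self.log_lambda))
        Q = X.shape[1]
        if lam == 0.0:
            if np.linalg.matrix_rank(X) < Q:
                warnings.warn(
                    "rank-deficient X with lambda=0: returning the "
                    "minimum-norm solution",
                    stacklevel=2,
                )
            self.W_ = np.linalg.lstsq(X, Y, rcond=None)[0]
        else:
            G = X.T @ X + lam * np.eye(Q)
            c, low = scipy.linalg.cho_factor(G)
            self.W_ = scipy.linalg.cho_solve((c, low), X.T @ Y)
        self.degenerate_voxels_ = np.array([], dtype=int)
        return self


class LassoConnectivity(_BaseConnectivity):
    """Lasso model minimizing ||Y - XW||^2 + lambda ||W||_1 per voxel.

    Solved by coordinate descent.  scikit-learn's Lasso minimizes
    (1/2T)||y - Xw||^2 + alpha ||w||_1, so alpha = exp(log_lambda) / (2T)
    reproduces the objective above exactly.  Voxels whose coordinate descent
    did not converge are recorded in ``nonconverged_voxels_``.
    """

    def __init__(
        self,
        log_lambda: float = 0.0,
        max_iter: int = 5000,
        tol: float = 1e-6,
    ):
        self.log_lambda = log_lambda
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X, Y = _validate_xy(X, Y)
        T = X.shape[0]
        lam = float(np.exp(self.log_lambda))
        if lam == 0.0:
            self.W_ = np.linalg.lstsq(X, Y, rcond=None)[0]
            self.nonconverged_voxels_ = np.array([], dtype=int)
            self.degenerate_voxels_ = np.array([], dtype=int)
            return self
        solver = _SkLasso(
            alpha=lam / (2.0 * T),
            fit_intercept=False,
            max_iter=self.max_iter,
            tol=self.tol,
            precompute=True,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            solver.fit(X, Y)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        coef = solver.coef_
        if coef.ndim == 1:
            coef = coef[None, :]
        self.W_ = coef.T
        if not converged:
            warnings.warn(
                "lasso coordinate descent did not converge for at least one "
                "voxel at max_iter",
                stacklevel=2,
            )
            self.nonconverged_voxels_ = np.arange(Y.shape[1])
        else:
            self.nonconverged_voxels_ = np.array([], dtype=int)
        self.degenerate_voxels_ = np.array([], dtype=int)
        return self


def _stack_pairs(pairs):
    if isinstance(pairs, CrossedPair):
        pairs = [pairs]
    X = np.vstack([p.X for p in pairs])
    Y = np.vstack([p.Y for p in pairs])
    meta = {
        "task_set": pairs[0].task_set,
        "directions": [(p.x_session, p.y_session) for p in pairs],
    }
    return X, Y, meta, list(pairs)


def fit_wta(pairs) -> ConnectivityWeights:
    """Fit the winner-take-all model on one or more crossed pairs."""
    X, Y, meta, _ = _stack_pairs(pairs)
    est = WTAConnectivity().fit(X, Y)
    return ConnectivityWeights(
        W=est.W_, method="wta", meta=meta,
        degenerate_voxels=est.degenerate_voxels_,
    )


def fit_ridge(pairs, log_lambda: float) -> ConnectivityWeights:
    """Fit the ridge model at a fixed log-lambda on one or more crossed pairs."""
    X, Y, meta, _ = _stack_pairs(pairs)
    est = RidgeConnectivity(log_lambda=log_lambda).fit(X, Y)
    return ConnectivityWeights(
        W=est.W_, method="ridge", log_lambda=float(log_lambda), meta=meta,
        degenerate_voxels=est.degenerate_voxels_,
    )


def fit_lasso(pairs, log_lambda: float, **kwargs) -> ConnectivityWeights:
    """Fit the lasso model at a fixed log-lambda on one or more crossed pairs."""
    X, Y, meta, _ = _stack_pairs(pairs)
    est = LassoConnectivity(log_lambda=log_lambda, **kwargs).fit(X, Y)
    meta = dict(meta, nonconverged_voxels=est.nonconverged_voxels_.tolist())
    return ConnectivityWeights(
        W=est.W_, method="lasso", log_lambda=float(log_lambda), meta=meta,
        degenerate_voxels=est.degenerate_voxels_,
    )


def _task_fold_masks(pair: CrossedPair, task_folds):
    """Timepoint masks per fold: a timepoint belongs to its regressor's task."""
    design = pair.design
    tp_reg = design.timepoint_regressor
    task_of_tp = np.array(
        ["" if k < 0 else design.task_ids[k] for k in tp_reg], dtype=object
    )
    masks = []
    for fold_tasks in task_folds:
        held = np.isin(task_of_tp, list(fold_tasks))
        active = tp_reg >= 0
        masks.append((active & ~held, held))
    return masks


def tune_lambda(
    train_pairs,
    method: str,
    grid=None,
    n_folds: int = 4,
    seed: int = 0,
) -> LambdaGrid:
    """Choose log-lambda by grid search with condition-wise cross-validation.

    Conditions of the training set are partitioned into ``n_folds``
    non-overlapping subsets at the task level (each task's conditions and
    its instruction regressor stay together).  Per fold, the model is fit on
    the time series reconstructed from the in-fold tasks and scored by the
    mean per-voxel Pearson r on the held-out tasks' series; the chosen
    lambda maximizes the fold-mean accuracy (ties go to the smaller
    lambda).  One lambda is shared across all voxels.
    """
    if method not in ("lasso", "ridge"):
        raise ValueError("method must be 'lasso' or 'ridge'")
    grid = default_grid() if grid is None else np.sort(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("empty log-lambda grid")
    if isinstance(train_pairs, CrossedPair):
        train_pairs = [train_pairs]
    tasks = sorted(set(train_pairs[0].design.task_ids))
    if len(tasks) < n_folds:
        raise ValueError(
            f"need at least n_folds={n_folds} tasks, have {len(tasks)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 509]))
    order = rng.permutation(len(tasks))
    task_folds = [
        [tasks[i] for i in order[f::n_folds]] for f in range(n_folds)
    ]
    pair_masks = [_task_fold_masks(p, task_folds) for p in train_pairs]
    fold_acc = np.zeros((n_folds, grid.size))
    for f in range(n_folds):
        Xtr = np.vstack([p.X[pair_masks[i][f][0]] for i, p in enumerate(train_pairs)])
        Ytr = np.vstack([p.Y[pair_masks[i][f][0]] for i, p in enumerate(train_pairs)])
        Xte = np.vstack([p.X[pair_masks[i][f][1]] for i, p in enumerate(train_pairs)])
        Yte = np.vstack([p.Y[pair_masks[i][f][1]] for i, p in enumerate(train_pairs)])
        # each fold's reconstructed series is its own training set: apply
        # the pipeline's standardization convention within the fold
        # (X re-z-scored, Y centered; the held-out X uses the training
        # fold's moments, and Pearson scoring is centering-invariant)
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd < 1e-12] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        Ytr = Ytr - Ytr.mean(axis=0)
        if method == "ridge":
            G = Xtr.T @ Xtr
            XtY = Xtr.T @ Ytr
            eye = np.eye(G.shape[0])
            for g, ll in enumerate(grid):
                W = scipy.linalg.solve(
                    G + np.exp(ll) * eye, XtY, assume_a="pos"
                )
                fold_acc[f, g] = np.nanmean(pearson_columns(Xte @ W, Yte))
        else:
            # warm-started coordinate-descent path, largest lambda first
            T = Xtr.shape[0]
            solver = _SkLasso(
                alpha=1.0,
                fit_intercept=False,
                warm_start=True,
                precompute=True,
                max_iter=300,
                tol=1e-4,
            )
            for g in range(grid.size - 1, -1, -1):
                solver.alpha = float(np.exp(grid[g]) / (2.0 * T))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    solver.fit(Xtr, Ytr)
                r = pearson_columns(Xte @ solver.coef_.T, Yte)
                # all-NaN means every prediction was constant (e.g. W = 0):
                # such a lambda can never be chosen
                fold_acc[f, g] = (
                    -np.inf if np.isnan(r).all() else np.nanmean(r)
                )
    cv_acc = fold_acc.mean(axis=0)
    chosen = float(grid[int(np.argmax(cv_acc))])  # argmax takes first (smallest)
    return LambdaGrid(
        log_lambdas=grid, cv_accuracy=cv_acc, chosen=chosen, fold_accuracy=fold_acc
    )


def group_average_weights(weights_list) -> ConnectivityWeights:
    """Element-wise mean of weight matrices across participants.

    All inputs must share method and shape.  Note that an averaged WTA
    matrix is generally no longer one-non-zero-per-column; this is flagged
    in the metadata.
    """
    weights_list = list(weights_list)
    if not weights_list:
        raise ValueError("empty weights list")
    method = weights_list[0].method
    shape = weights_list[0].W.shape
    for w in weights_list[1:]:
        if w.method != method:
            raise ValueError("cannot average weights of different methods")
        if w.W.shape != shape:
            raise ValueError(
                f"shape mismatch: {w.W.shape} vs {shape}"
            )
    W = np.mean([w.W for w in weights_list], axis=0)
    meta = {
        "group_average": True,
        "n_participants": len(weights_list),
        "log_lambdas": [w.log_lambda for w in weights_list],
    }
    if method == "wta":
        meta["one_per_column"] = False
    return ConnectivityWeights(
        W=W,
        method=method,
        log_lambda=weights_list[0].log_lambda,
        meta=meta,
    )
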