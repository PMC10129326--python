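"""Crossed out-of-sample evaluation and model-dependent noise ceilings.

A model's predictive accuracy is the per-voxel Pearson correlation between
predicted and observed cerebellar fitted time series, computed with crossed
sessions (cortex from one session, cerebellum from the other) and averaged
over both crossed directions.

Even the true connectivity model cannot reach r = 1: both the cerebellar
target and the cortical predictors carry measurement noise.  Writing a
session's cerebellar series as Y_j = Y* + eps and the model prediction as
X_j W = X*W + noise, the split-half reliabilities

    r(Y1, Y2)   = sigma_Y^2 / (sigma_Y^2 + sigma_eps^2)
    r(X1W, X2W) = sigma_Y^2 / (sigma_Y^2 + sigma_XW^2)

combine into the expected correlation of the true model,

    r_ceil = sigma_Y^2 / sqrt((sigma_Y^2 + sigma_XW^2)(sigma_Y^2 + sigma_eps^2))
           = sqrt(r(Y1, Y2) * r(X1W, X2W)),

the positive root of the reliability product.  Because r(X1W, X2W) involves
the model's own weights, the ceiling is model dependent.  Normalized
accuracy is r_obs / r_ceil; voxels with non-positive reliabilities have no
defined ceiling and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import pearson_columns
from .estimators import ConnectivityWeights
from .reconstruction import CrossedPair, FittedData

__all__ = [
    "CeilingComponents",
    "EvaluationResult",
    "predict",
    "predictive_accuracy",
    "noise_ceiling",
    "evaluate_model",
    "session_ceiling_oddeven",
]


@dataclass
class CeilingComponents:
    """Split-half reliabilities and the per-voxel noise ceiling they imply."""

    reliability_Y: np.ndarray       # per-voxel r(Y1, Y2)
    reliability_XW: np.ndarray      # per-voxel r(X1 W, X2 W)
    r_ceiling: np.ndarray           # sqrt of the product, NaN where undefined
    undefined: np.ndarray           # boolean mask of voxels without a ceiling


@dataclass
class EvaluationResult:
    """Per-voxel observed accuracy, ceiling, and ceiling-normalized accuracy."""

    r_obs: np.ndarray
    r_per_direction: np.ndarray     # (2, P) the two crossed directions
    reliability_Y: np.ndarray
    reliability_XW: np.ndarray
    r_ceiling: np.ndarray
    R_norm: np.ndarray              # r_obs / r_ceiling, NaN where undefined
    undefined: np.ndarray
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        defined = ~self.undefined
        return {
            "mean_r_obs": float(np.nanmean(self.r_obs)),
            "mean_r_ceiling": float(np.nanmean(self.r_ceiling[defined]))
            if defined.any() else float("nan"),
            "mean_R_norm": float(np.nanmean(self.R_norm[defined]))
            if defined.any() else float("nan"),
            "n_voxels": int(self.r_obs.size),
            "n_undefined": int(self.undefined.sum()),
        }


def predict(weights: ConnectivityWeights, X) -> np.ndarray:
    """Predicted cerebellar series Y_hat = X W."""
    Xmat = X.X if isinstance(X, FittedData) else np.asarray(X, dtype=float)
    if Xmat.shape[1] != weights.Q:
        raise ValueError(
            f"X has {Xmat.shape[1]} parcels but weights expect {weights.Q}"
        )
    return Xmat @ weights.W


def predictive_accuracy(
    y_pred: np.ndarray, y_obs: np.ndarray
) -> np.ndarray:
    """Per-voxel Pearson r between predicted and observed series.

    Zero-variance voxels yield NaN and are excluded from any summary the
    caller computes with nan-aware reductions.
    """
    return pearson_columns(np.asarray(y_pred, float), np.asarray(y_obs, float))


def _crossed_accuracy(weights, pairs, allow_same_session):
    rs = []
    for pair in pairs:
        if not pair.crossed and not allow_same_session:
            raise ValueError(
                "X and Y come from the same session "
                f"({pair.x_session}); crossed evaluation required "
                "(pass allow_same_session=True to override)"
            )
        rs.append(predictive_accuracy(predict(weights, pair.X), pair.Y))
    return np.array(rs)


def noise_ceiling(
    X1: np.ndarray,
    X2: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    weights: ConnectivityWeights,
) -> CeilingComponents:
    """Model-dependent noise ceiling from two sessions of the evaluation set.

    ``X1, X2`` and ``Y1, Y2`` are the two sessions' fitted series on a
    common time base.  Voxels where either reliability is non-positive get
    an undefined (NaN) ceiling.
    """
    rel_Y = pearson_columns(np.asarray(Y1, float), np.asarray(Y2, float))
    pred1 = predict(weights, X1)
    pred2 = predict(weights, X2)
    rel_XW = pearson_columns(pred1, pred2)
    with np.errstate(invalid="ignore"):
        prod = rel_Y * rel_XW
        undefined = ~((rel_Y > 0) & (rel_XW > 0))
        r_ceiling = np.where(undefined, np.nan, np.sqrt(np.abs(prod)))
    return CeilingComponents(
        reliability_Y=rel_Y,
        reliability_XW=rel_XW,
        r_ceiling=r_ceiling,
        undefined=undefined,
    )


def evaluate_model(
    weights: ConnectivityWeights,
    session1: FittedData,
    session2: FittedData,
    allow_same_session: bool = False,
) -> EvaluationResult:
    """Full crossed evaluation of a fitted model on a two-session test set.

    Observed accuracy averages the two crossed directions (X2 -> Y1 and
    X1 -> Y2); reliabilities use each raw session once.
    """
    from .reconstruction import make_crossed_pairs

    if session1.task_set != session2.task_set:
        raise ValueError("evaluation sessions must share a task set")
    pairs = make_crossed_pairs(session1, session2)
    r_dir = _crossed_accuracy(weights, pairs, allow_same_session)
    r_obs = r_dir.mean(axis=0)
    ceil = noise_ceiling(session1.X, session2.X, session1.Y, session2.Y, weights)
    with np.errstate(invalid="ignore", divide="ignore"):
        R_norm = np.where(ceil.undefined, np.nan, r_obs / ceil.r_ceiling)
    return EvaluationResult(
        r_obs=r_obs,
        r_per_direction=r_dir,
        reliability_Y=ceil.reliability_Y,
        reliability_XW=ceil.reliability_XW,
        r_ceiling=ceil.r_ceiling,
        R_norm=R_norm,
        undefined=ceil.undefined,
        meta={
            "directions": [(p.x_session, p.y_session) for p in pairs],
            "method": weights.method,
            "log_lambda": weights.log_lambda,
        },
    )


def session_ceiling_oddeven(
    recordings,
    weights: ConnectivityWeights,
    standardize: bool = True,
):
    """Per-session noise ceilings from odd/even run splits.

    For datasets evaluated session by session (e.g. generalization to new
    participants with group-averaged weights), reliabilities are computed
    between the fitted series reconstructed from odd and from even runs
    within each session; the ceiling combines them exactly as the
    between-session ceiling does.  Observed accuracy is crossed across the
    run halves (odd cortex predicting even cerebellum and vice versa) and
    normalized per session; returns a list of per-session
    ``EvaluationResult`` plus the across-session mean normalized accuracy.
    """
    from .reconstruction import (
        fitted_timeseries, snr_normalize, zstandardize,
    )

    results = []
    for rec in recordings:
        n_runs = rec.X_run_betas.shape[0]
        if n_runs < 2:
            raise ValueError("odd/even split needs at least 2 runs")
        design = rec.schedule.design(run=None)
        odd, even = np.arange(n_runs) % 2 == 1, np.arange(n_runs) % 2 == 0
        halves = {}
        for name, sel in (("odd", odd), ("even", even)):
            Xb = rec.X_run_betas[sel].mean(axis=0)
            Yb = rec.Y_run_betas[sel].mean(axis=0)
            X = fitted_timeseries(design, Xb)
            X, _ = snr_normalize(X, rec.residual_sd_cortex)
            if standardize:
                X, _ = zstandardize(X)
            Y = fitted_timeseries(design, Yb)
            Y, _ = snr_normalize(Y, rec.residual_sd_cerebellum)
            halves[name] = (X, Y)
        X_o, Y_o = halves["odd"]
        X_e, Y_e = halves["even"]
        ceil = noise_ceiling(X_o, X_e, Y_o, Y_e, weights)
        r_dir = np.array([
            predictive_accuracy(predict(weights, X_o), Y_e),
            predictive_accuracy(predict(weights, X_e), Y_o),
        ])
        r_obs = r_dir.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R_norm = np.where(ceil.undefined, np.nan, r_obs / ceil.r_ceiling)
        results.append(
            EvaluationResult(
                r_obs=r_obs,
                r_per_direction=r_dir,
                reliability_Y=ceil.reliability_Y,
                reliability_XW=ceil.reliability_XW,
                r_ceiling=ceil.r_ceiling,
                R_norm=R_norm,
                undefined=ceil.undefined,
                meta={"session_id": rec.session_id, "split": "odd_even"},
            )
        )
    mean_norm = float(
        np.nanmean([np.nanmean(r.R_norm) for r in results])
    )
    return results, mean_norm
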