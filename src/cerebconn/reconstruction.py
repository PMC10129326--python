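"""From per-session GLM outputs to the fitted time series the models run on.

The connectivity models never see raw time series.  Each session's
run-averaged condition betas are multiplied with the boxcar design matrix to
give the task-evoked "fitted" time series, divided by the GLM residual SD
(SNR normalization), averaged within cortical parcels, and the cortical side
z-standardized.  Because regressor durations differ (5 s instructions vs
longer condition blocks), this reweights each condition's leverage on all
covariances by the diagonal (and off-diagonal) structure of Z'Z.

Training and evaluation are "crossed": a pair combines cortical data from
one session with cerebellar data from the other session of the same task
set, on a shared canonical design, so that within-session noise shared
between cortex and cerebellum cannot masquerade as connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import SessionRecording, TaskDesign

__all__ = [
    "FittedData",
    "CrossedPair",
    "fitted_timeseries",
    "snr_normalize",
    "parcel_average",
    "zstandardize",
    "reconstruct_session",
    "make_crossed_pairs",
]


@dataclass
class FittedData:
    """Normalized fitted time series of one session (cortex X, cerebellum Y)."""

    X: np.ndarray                   # (T, Q), z-standardized if `standardized`
    Y: np.ndarray                   # (T, P)
    session_id: str
    task_set: str
    standardized: bool
    design: TaskDesign
    dropped_cortex: np.ndarray | None = None   # indices dropped for degeneracy
    dropped_cerebellum: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def Q(self) -> int:
        return self.X.shape[1]

    @property
    def P(self) -> int:
        return self.Y.shape[1]


@dataclass
class CrossedPair:
    """Cortical series from one session paired with cerebellar from the other."""

    X: np.ndarray                   # (T, Q)
    Y: np.ndarray                   # (T, P)
    x_session: str
    y_session: str
    task_set: str
    design: TaskDesign

    @property
    def crossed(self) -> bool:
        return self.x_session != self.y_session


def fitted_timeseries(design, betas: np.ndarray) -> np.ndarray:
    """Fitted time series Z @ betas; ``design`` is a TaskDesign or (T, K) array."""
    Z = design.matrix if isinstance(design, TaskDesign) else np.asarray(design)
    betas = np.asarray(betas)
    if Z.shape[1] != betas.shape[0]:
        raise ValueError(
            f"design has {Z.shape[1]} regressors but betas has {betas.shape[0]} rows"
        )
    return Z @ betas


def snr_normalize(fitted: np.ndarray, residual_sd: np.ndarray):
    """Divide each column by its GLM residual SD.

    Columns with non-positive SD are dropped with a warning.  Returns
    ``(normalized, kept_indices)``.
    """
    fitted = np.asarray(fitted, dtype=float)
    residual_sd = np.asarray(residual_sd, dtype=float)
    if fitted.shape[1] != residual_sd.shape[0]:
        raise ValueError("residual_sd length must match number of columns")
    ok = residual_sd > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} channel(s) with non-positive residual SD",
            stacklevel=2,
        )
    kept = np.flatnonzero(ok)
    return fitted[:, kept] / residual_sd[kept][None, :], kept


def parcel_average(voxel_fitted: np.ndarray, parcel_assignment: np.ndarray):
    """Average columns within parcels; empty parcels are dropped with a warning.

    Returns ``(T x Q matrix, parcel_ids)`` with parcels in sorted id order.
    """
    voxel_fitted = np.asarray(voxel_fitted, dtype=float)
    parcel_assignment = np.asarray(parcel_assignment)
    if voxel_fitted.shape[1] != parcel_assignment.shape[0]:
        raise ValueError("one parcel assignment per column required")
    ids = np.unique(parcel_assignment)
    if ids.size == 0:
        raise ValueError("no parcels present in assignment")
    out = np.column_stack(
        [voxel_fitted[:, parcel_assignment == q].mean(axis=1) for q in ids]
    )
    return out, ids


def zstandardize(X: np.ndarray, tol: float = 1e-12):
    """Column-wise z-scores with the population convention (divisor T).

    Zero-variance columns are dropped with a warning.  Returns
    ``(standardized, kept_indices)``.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    ok = sd > tol
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} zero-variance column(s) before z-scoring",
            stacklevel=2,
        )
    kept = np.flatnonzero(ok)
    return (X[:, kept] - mu[kept]) / sd[kept], kept


def reconstruct_session(
    recording: SessionRecording,
    design: TaskDesign | None = None,
    standardize: bool = True,
    parcel_assignment: np.ndarray | None = None,
) -> FittedData:
    """Full reconstruction for one session.

    ``design`` defaults to the session schedule's canonical design (blocks in
    task order), so all sessions of a task set are reconstructed on one time
    base and can be crossed.  ``parcel_assignment`` maps cortical columns to
    parcels when the cortical betas are voxel- rather than parcel-resolved.
    """
    if design is None:
        design = recording.schedule.design(run=None)
    X = fitted_timeseries(design, recording.X_betas)
    X, kept_x = snr_normalize(X, recording.residual_sd_cortex)
    if parcel_assignment is not None:
        X, _ = parcel_average(X, np.asarray(parcel_assignment)[kept_x])
    Y = fitted_timeseries(design, recording.Y_betas)
    Y, kept_y = snr_normalize(Y, recording.residual_sd_cerebellum)
    dropped_x = np.setdiff1d(np.arange(recording.X_betas.shape[1]), kept_x)
    dropped_y = np.setdiff1d(np.arange(recording.Y_betas.shape[1]), kept_y)
    if standardize:
        X, kept_z = zstandardize(X)
        if parcel_assignment is None and kept_z.size < kept_x.size:
            dropped_x = np.union1d(dropped_x, kept_x[np.setdiff1d(
                np.arange(kept_x.size), kept_z)])
    return FittedData(
        X=X,
        Y=Y,
        session_id=recording.session_id,
        task_set=recording.schedule.task_set,
        standardized=standardize,
        design=design,
        dropped_cortex=dropped_x,
        dropped_cerebellum=dropped_y,
    )


def make_crossed_pairs(session1: FittedData, session2: FittedData):
    """Return the two crossed pairs (X2 -> Y1) and (X1 -> Y2).

    Both sessions must be reconstructed on the same canonical condition
    ordering (same task set, same design shape); no pair combines X and Y
    from the same session.
    """
    if session1.task_set != session2.task_set:
        raise ValueError(
            f"sessions come from different task sets: "
            f"{session1.task_set!r} vs {session2.task_set!r}"
        )
    if session1.T != session2.T:
        raise ValueError("sessions reconstructed on different time bases")
    pair_a = CrossedPair(
        X=session2.X,
        Y=session1.Y,
        x_session=session2.session_id,
        y_session=session1.session_id,
        task_set=session1.task_set,
        design=session1.design,
    )
    pair_b = CrossedPair(
        X=session1.X,
        Y=session2.Y,
        x_session=session1.session_id,
        y_session=session2.session_id,
        task_set=session1.task_set,
        design=session2.design,
    )
    return [pair_a, pair_b]
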