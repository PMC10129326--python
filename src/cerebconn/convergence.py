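"""Convergence of cortical inputs per cerebellar voxel.

Two complementary metrics quantify how much of the cortex feeds a voxel:

* input area — the fraction of cortical parcels with a retained weight.
  Lasso and WTA produce exact zeros, so non-zeros are counted directly; for
  ridge, whose weights are never exactly zero, a weight is retained when it
  exceeds the mean + 1 SD of the whole weight matrix.

* spherical dispersion — one minus the length of the resultant of the
  parcel-center unit vectors v_i weighted by the (non-negative) connectivity
  weights, computed per hemisphere and combined across hemispheres weighted
  by each hemisphere's summed non-negative weight.  0 means all input comes
  from one cortical location; values toward 1 mean input spread symmetrically
  over the hemisphere sphere.

By default the weights inside the dispersion are normalized to unit sum per
hemisphere, which keeps the metric scale invariant and inside [0, 1]; the
literal 1/Q_h averaging variant is available via ``normalization="literal"``
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import ConnectivityWeights
from .synthetic_data import ParcelSet, RegionMap

__all__ = [
    "ConvergenceResult",
    "input_area",
    "spherical_dispersion",
    "aggregate_by_region",
    "convergence_metrics",
]


@dataclass
class ConvergenceResult:
    """Per-voxel convergence metrics with region-level summaries."""

    input_area: np.ndarray          # (P,) fraction of parcels retained
    dispersion: np.ndarray          # (P,) combined spherical variance, NaN = undefined
    var_by_hemisphere: dict         # 'L'/'R' -> (P,) per-hemisphere variance
    region_summary: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def input_area(
    weights: ConnectivityWeights,
    ridge_threshold: str = "global",
) -> np.ndarray:
    """Fraction of cortical parcels contributing to each voxel's prediction.

    For lasso and WTA the count is of exactly non-zero coefficients
    (negative non-zeros still count as inputs).  For ridge, a coefficient is
    retained iff it exceeds mean + 1 SD; with ``ridge_threshold="global"``
    (default) the mean and SD are taken over the entire weight matrix, with
    ``"per_voxel"`` over each voxel's column.
    """
    W = np.asarray(weights.W, dtype=float)
    if W.size == 0:
        raise ValueError("empty weight matrix")
    Q = W.shape[0]
    if weights.method in ("lasso", "wta"):
        retained = W != 0
    elif weights.method == "ridge":
        if ridge_threshold == "global":
            thr = W.mean() + W.std()
            retained = W > thr
        elif ridge_threshold == "per_voxel":
            thr = W.mean(axis=0) + W.std(axis=0)
            retained = W > thr[None, :]
        else:
            raise ValueError(f"unknown ridge_threshold {ridge_threshold!r}")
    else:
        raise ValueError(f"unknown method {weights.method!r}")
    return retained.sum(axis=0) / Q


def spherical_dispersion(
    weights,
    parcels: ParcelSet,
    normalization: str = "unit_sum",
):
    """Spherical variance of each voxel's input weights, per hemisphere.

    Negative weights are set to zero first.  Per hemisphere h with parcel
    unit vectors v_i and non-negative weights w_i:

        unit_sum (default): var_h = 1 - || sum_i (w_i / sum_j w_j) v_i ||
        literal:            var_h = 1 - || (1 / Q_h) sum_i w_i v_i ||

    The combined value averages the hemispheres weighted by each
    hemisphere's summed non-negative weight s_h.  Voxels with s_h = 0 have
    var_h undefined (NaN) for that hemisphere; with no positive weight in
    either hemisphere the combined value is undefined.

    Returns ``(combined, var_by_hemisphere)``.
    """
    W = weights.W if isinstance(weights, ConnectivityWeights) else np.asarray(weights)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != parcels.Q:
        raise ValueError(
            f"weight matrix has {W.shape[0]} parcels but parcel set has {parcels.Q}"
        )
    if normalization not in ("unit_sum", "literal"):
        raise ValueError(f"unknown normalization {normalization!r}")
    Wpos = np.clip(W, 0.0, None)
    P = W.shape[1]
    var_h = {}
    s_h = {}
    for h in ("L", "R"):
        sel = parcels.hemisphere == h
        V = parcels.centers[sel]            # (Q_h, 3)
        w = Wpos[sel]                       # (Q_h, P)
        s = w.sum(axis=0)                   # (P,)
        resultant = np.linalg.norm(V.T @ w, axis=0)  # || sum w_i v_i ||
        with np.errstate(invalid="ignore", divide="ignore"):
            if normalization == "unit_sum":
                var = 1.0 - resultant / s
            else:
                var = 1.0 - resultant / sel.sum()
        var = np.where(s > 0, var, np.nan)
        var_h[h] = var
        s_h[h] = s
    total = s_h["L"] + s_h["R"]
    num = np.zeros(P)
    for h in ("L", "R"):
        num += np.where(s_h[h] > 0, s_h[h] * np.nan_to_num(var_h[h]), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(total > 0, num / total, np.nan)
    return combined, var_h


def aggregate_by_region(
    metric: np.ndarray, region_map: RegionMap
) -> pd.DataFrame:
    """Per-region mean, SD and counts of a per-voxel metric.

    Undefined (NaN) voxels are excluded from the mean/SD and counted in
    ``n_undefined``; a region with no defined voxel gets NaN summaries.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.shape[0] != region_map.n_voxels:
        raise ValueError("metric and region map must share voxel indexing")
    rows = []
    for r in region_map.regions:
        vals = metric[region_map.voxel_regions == r]
        defined = vals[~np.isnan(vals)]
        rows.append(
            {
                "region": int(r),
                "name": region_map.region_names[int(r) - 1],
                "mean": float(defined.mean()) if defined.size else float("nan"),
                "sd": float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
                "n": int(defined.size),
                "n_undefined": int(np.isnan(vals).sum()),
            }
        )
    return pd.DataFrame(rows)


def convergence_metrics(
    weights: ConnectivityWeights,
    parcels: ParcelSet,
    region_map: RegionMap | None = None,
    ridge_threshold: str = "global",
    normalization: str = "unit_sum",
) -> ConvergenceResult:
    """Input area plus spherical dispersion, optionally aggregated by region."""
    area = input_area(weights, ridge_threshold=ridge_threshold)
    combined, var_h = spherical_dispersion(
        weights, parcels, normalization=normalization
    )
    summary = None
    if region_map is not None:
        a = aggregate_by_region(area, region_map).rename(
            columns={"mean": "input_area_mean", "sd": "input_area_sd"}
        )
        d = aggregate_by_region(combined, region_map)[["region", "mean", "sd"]]
        d = d.rename(columns={"mean": "dispersion_mean", "sd": "dispersion_sd"})
        summary = a.merge(d, on="region")
    return ConvergenceResult(
        input_area=area,
        dispersion=combined,
        var_by_hemisphere=var_h,
        region_summary=summary,
        meta={
            "method": weights.method,
            "ridge_threshold": ridge_threshold if weights.method == "ridge" else None,
            "normalization": normalization,
        },
    )
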