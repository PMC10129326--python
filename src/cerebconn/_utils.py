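"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation between two (T, P) matrices.

    Columns where either input has zero variance yield NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = np.einsum("tp,tp->p", Ac, Bc)
    den = np.sqrt(np.einsum("tp,tp->p", Ac, Ac) * np.einsum("tp,tp->p", Bc, Bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r
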