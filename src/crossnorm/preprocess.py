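"""Log transformation, quantile normalization and the detection-p filter.

Quantile normalization forces every sample column onto the identical
empirical distribution (the row-means of the column-sorted matrix); ties
within a column receive the mean of the reference values at their tied
ranks.  The detection filter removes a gene when it is undetected
(p > alpha) in at least ``n_samples - margin`` samples, i.e. keeps genes
detected in at least ``margin + 1`` samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["log2_transform", "quantile_normalize", "detection_filter"]


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise y = log2(x + offset) on a linear-scale matrix."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    values = matrix.to_numpy(dtype=float) + offset
    bad = np.argwhere(values <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"nonpositive value at gene {matrix.index[r]!r}, sample "
            f"{matrix.columns[c]!r} (value+offset = {values[r, c]}); "
            "supply a positive offset explicitly"
        )
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    Reference distribution = row means of each column sorted ascending.
    Tied values in a column all receive the mean of the reference values
    occupying their tied rank positions.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    reference = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(col)
        ranked[order] = reference
        # average the reference over each tied block
        sorted_col = col[order]
        i = 0
        n = len(col)
        while i < n:
            k = i + 1
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            if k - i > 1:
                ranked[order[i:k]] = reference[i:k].mean()
            i = k
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    matrix: pd.DataFrame,
    detect: pd.DataFrame,
    alpha: float = 0.05,
    margin: int = 3,
) -> pd.DataFrame:
    """Drop genes undetected (p > alpha) in >= n_samples - margin samples."""
    if matrix.shape != detect.shape:
        raise ValueError(
            f"shape mismatch: expression {matrix.shape} vs detection {detect.shape}"
        )
    if not (matrix.index.equals(detect.index) and matrix.columns.equals(detect.columns)):
        raise ValueError("expression and detection matrices must share IDs and order")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    n = matrix.shape[1]
    if not 0 <= margin < n:
        raise ValueError(f"margin must satisfy 0 <= margin < n_samples ({n})")
    detected = (detect.to_numpy(dtype=float) <= alpha).sum(axis=1)
    keep = detected >= margin + 1
    return matrix.loc[keep].copy()
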