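"""Significance Analysis of Microarrays: moderated d statistic and
permutation-based FDR, in unpaired and paired flavours.

The statistic is d = r / (s + s0): for two unpaired classes r is the
difference of class means and s the pooled standard error; in the paired
design r is the mean within-pair difference and s its standard error.  The
fudge factor s0 stabilizes d for low-variance genes and is chosen to
flatten the dependence of |d| on s.  FDR estimation follows the original
permutation scheme: expected order statistics of d under label
permutations (sign flips within pairs for the paired design), asymmetric
delta thresholds, and the median permutation false-positive count over
the number of genes called (pi0 fixed at 1, conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabels",
    "SamResult",
    "sam_statistic",
    "sam_paired",
    "choose_s0",
    "sam_fdr",
    "top_n",
    "overlap",
]


@dataclass
class ClassLabels:
    """sample -> class {1, 2}, optionally with pair IDs for paired designs."""

    classes: pd.Series
    pairs: pd.Series | None = None

    def __post_init__(self):
        self.classes = pd.Series(self.classes).astype(int)
        if not set(self.classes.unique()) <= {1, 2}:
            raise ValueError("classes must be coded 1/2")
        if (self.classes == 1).sum() == 0 or (self.classes == 2).sum() == 0:
            raise ValueError("both classes must be non-empty")
        if self.pairs is not None:
            self.pairs = pd.Series(self.pairs).astype(str).loc[self.classes.index]

    @property
    def paired(self) -> bool:
        return self.pairs is not None

    def for_columns(self, columns) -> "ClassLabels":
        cls = self.classes.loc[list(columns)]
        pairs = self.pairs.loc[list(columns)] if self.paired else None
        return ClassLabels(cls, pairs)


@dataclass
class SamResult:
    """Per-gene SAM statistics plus the delta-grid FDR table."""

    scores: pd.DataFrame  # columns r, s, d
    s0: float
    fdr_table: pd.DataFrame  # delta, n_called, median_false, fdr
    n_perm: int
    seed: int | None = None
    paired: bool = False
    permutations_enumerated: bool = False
    calls: dict = field(default_factory=dict)  # delta -> called gene index


def _check_matrix_labels(matrix, labels: ClassLabels):
    missing = matrix.columns.difference(labels.classes.index)
    if len(missing):
        raise ValueError(f"samples without class label: {list(missing[:5])}")
    return labels.for_columns(matrix.columns)


def sam_statistic(matrix: pd.DataFrame, labels: ClassLabels, s0: float = 0.0):
    """Unpaired SAM scores: r = mean2 - mean1, s = pooled SE, d = r/(s+s0)."""
    labels = _check_matrix_labels(matrix, labels)
    y = labels.classes.to_numpy()
    X = matrix.to_numpy(dtype=float)
    return _sam_unpaired_arrays(X, y, s0, matrix.index)


def _sam_unpaired_arrays(X, y, s0, index):
    i1, i2 = np.flatnonzero(y == 1), np.flatnonzero(y == 2)
    n1, n2 = i1.size, i2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs >= 2 samples")
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    m1 = X[:, i1].mean(axis=1)
    m2 = X[:, i2].mean(axis=1)
    r = m2 - m1
    ss = ((X[:, i1] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, i2] - m2[:, None]) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame({"r": r, "s": s, "d": d}, index=index)


def sam_paired(matrix: pd.DataFrame, labels: ClassLabels, s0: float = 0.0):
    """Paired SAM scores on within-pair differences (class2 - class1)."""
    labels = _check_matrix_labels(matrix, labels)
    if not labels.paired:
        raise ValueError("labels carry no pair IDs")
    diffs, _ = _pair_differences(matrix, labels)
    return _sam_paired_arrays(diffs.to_numpy(), s0, matrix.index, diffs.columns)


def _pair_differences(matrix, labels: ClassLabels):
    cls, pairs = labels.classes, labels.pairs
    bad = []
    cols1, cols2, ids = [], [], []
    for pid, idx in pairs.groupby(pairs).groups.items():
        sub = cls.loc[idx]
        if sorted(sub.tolist()) != [1, 2]:
            bad.append(pid)
            continue
        cols1.append(sub.index[sub.to_numpy() == 1][0])
        cols2.append(sub.index[sub.to_numpy() == 2][0])
        ids.append(pid)
    if bad:
        raise ValueError(f"incomplete pairs: {bad}")
    if len(ids) < 2:
        raise ValueError("need >= 2 complete pairs")
    diffs = pd.DataFrame(
        matrix[cols2].to_numpy() - matrix[cols1].to_numpy(),
        index=matrix.index,
        columns=ids,
    )
    return diffs, ids


def _sam_paired_arrays(Z, s0, index, pair_ids=None):
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    npair = Z.shape[1]
    r = Z.mean(axis=1)
    s = Z.std(axis=1, ddof=1) / np.sqrt(npair)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame({"r": r, "s": s, "d": d}, index=index)


def choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Pick s0 minimizing the coefficient of variation of |d| across s bins.

    Candidates are the 0,5,...,100 percentiles of s; genes are split into
    100 equal-count bins of s and the CV of the bin-wise median |d| is
    minimized (ties -> smaller s0).
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.ptp(s) <= 0:
        import warnings

        warnings.warn("choose_s0: gene scatter is constant; returning 5th percentile")
        return float(np.percentile(s, 5))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="mergesort")
    n_bins = min(100, max(2, s.size // 2))
    bins = np.array_split(order, n_bins)
    best = None
    for cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r / (s + cand)
        med = np.array([np.median(np.abs(d[b])) for b in bins])
        mu = med.mean()
        cv = med.std(ddof=1) / mu if mu > 0 else np.inf
        if best is None or cv < best[0] - 1e-12:
            best = (cv, float(cand))
    return best[1]


def _permutation_plan(labels: ClassLabels, n_perm: int, rng):
    """Label permutations (unpaired) or sign-flip patterns (paired).

    Returns (list-of-assignments, enumerated flag).  Full enumeration is
    used whenever the permutation space is no larger than n_perm.
    """
    if labels.paired:
        npair = labels.pairs.nunique()
        total = 2**npair
        if total <= n_perm:
            signs = [
                np.array([1 if (m >> b) & 1 else -1 for b in range(npair)])
                for m in range(total)
            ]
            return signs, True
        return [rng.choice([-1, 1], size=npair) for _ in range(n_perm)], False
    y = labels.classes.to_numpy()
    n = y.size
    n1 = int((y == 1).sum())
    from math import comb

    total = comb(n, n1)
    if total <= n_perm:
        perms = []
        for ones in combinations(range(n), n1):
            yy = np.full(n, 2)
            yy[list(ones)] = 1
            perms.append(yy)
        return perms, True
    perms = []
    for _ in range(n_perm):
        yy = np.full(n, 2)
        yy[rng.choice(n, size=n1, replace=False)] = 1
        perms.append(yy)
    return perms, False


def sam_fdr(
    matrix: pd.DataFrame,
    labels: ClassLabels,
    s0: float | str = "auto",
    n_perm: int = 200,
    delta_grid=None,
    seed: int | None = None,
) -> SamResult:
    """SAM with permutation FDR over a grid of delta thresholds."""
    labels = _check_matrix_labels(matrix, labels)
    if delta_grid is None:
        delta_grid = np.round(np.arange(0.1, 5.01, 0.1), 10)
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delta grid is empty")
    rng = np.random.default_rng(seed)

    if labels.paired:
        diffs, _ = _pair_differences(matrix, labels)
        Z = diffs.to_numpy()
        base = _sam_paired_arrays(Z, 0.0, matrix.index)
    else:
        X = matrix.to_numpy(dtype=float)
        y = labels.classes.to_numpy()
        base = _sam_unpaired_arrays(X, y, 0.0, matrix.index)
    if s0 == "auto":
        s0 = choose_s0(base["r"].to_numpy(), base["s"].to_numpy())
    s0 = float(s0)
    if labels.paired:
        scores = _sam_paired_arrays(Z, s0, matrix.index)
    else:
        scores = _sam_unpaired_arrays(X, y, s0, matrix.index)

    plan, enumerated = _permutation_plan(labels, n_perm, rng)
    perm_d = np.empty((len(plan), matrix.shape[0]))
    for b, assign in enumerate(plan):
        if labels.paired:
            perm_d[b] = _sam_paired_arrays(Z * assign[None, :], s0, matrix.index)[
                "d"
            ].to_numpy()
        else:
            perm_d[b] = _sam_unpaired_arrays(X, assign, s0, matrix.index)[
                "d"
            ].to_numpy()

    d = scores["d"].to_numpy()
    order = np.argsort(d, kind="mergesort")
    d_sorted = d[order]
    dbar = np.sort(perm_d, axis=1).mean(axis=0)

    rows = []
    calls = {}
    G = d.size
    for delta in delta_grid:
        diff = d_sorted - dbar
        up = np.flatnonzero(diff > delta)
        lo = np.flatnonzero(diff < -delta)
        cut_up = d_sorted[up].min() if up.size else np.inf
        cut_lo = d_sorted[lo].max() if lo.size else -np.inf
        called = (d >= cut_up) | (d <= cut_lo)
        n_called = int(called.sum())
        false_counts = ((perm_d >= cut_up) | (perm_d <= cut_lo)).sum(axis=1)
        med_false = float(np.median(false_counts))
        fdr = min(med_false / n_called, 1.0) if n_called else 0.0
        rows.append((float(delta), n_called, med_false, fdr))
        calls[float(delta)] = matrix.index[called]
    fdr_table = pd.DataFrame(rows, columns=["delta", "n_called", "median_false", "fdr"])

    return SamResult(
        scores=scores,
        s0=s0,
        fdr_table=fdr_table,
        n_perm=len(plan),
        seed=seed,
        paired=labels.paired,
        permutations_enumerated=enumerated,
        calls=calls,
    )


def top_n(result: SamResult, n: int):
    """Top n genes by |d| descending, ties broken lexicographically."""
    d = result.scores["d"]
    if n > d.size:
        raise ValueError(f"n={n} exceeds number of genes ({d.size})")
    ranking = sorted(d.index, key=lambda g: (-abs(d[g]), g))
    return list(ranking[:n])


def overlap(list_a, list_b, n: int):
    """Overlap of the first n entries of two ranked gene lists."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(list_a) < n or len(list_b) < n:
        raise ValueError("lists shorter than n")
    count = len(set(list_a[:n]) & set(list_b[:n]))
    return count, 100.0 * count / n
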