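"""Comparison metrics and unsupervised views: pairwise correlation,
hierarchical clustering (1 - Pearson r, average linkage), classical MDS,
fold-change concordance, most-variable-gene selection and nearest-centroid
subtype assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "pairwise_correlation",
    "hcluster",
    "mds_embed",
    "foldchange_concordance",
    "most_variable_genes",
    "CentroidSet",
    "assign_subtypes",
    "agreement",
]


def pairwise_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation over genes.

    Zero-variance samples get NaN off-diagonal entries (flagged undefined)
    but keep a unit diagonal.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    bad = sd == 0
    R[bad, :] = np.nan
    R[:, bad] = np.nan
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=matrix.columns, columns=matrix.columns)


def _corr_distance(matrix: pd.DataFrame, on: str) -> tuple[pd.Index, np.ndarray]:
    data = matrix.T if on == "samples" else matrix
    ids = data.index
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = ids[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"constant item {bad!r}: correlation distance undefined")
    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    return ids, D


def hcluster(matrix: pd.DataFrame, on: str = "samples"):
    """Average-linkage agglomeration with distance 1 - Pearson r.

    Returns (linkage matrix in scipy format, leaf IDs in dendrogram order).
    Items are pre-sorted by ID so equal-distance merges resolve
    deterministically.
    """
    if on not in ("samples", "genes"):
        raise ValueError("on must be 'samples' or 'genes'")
    ids, D = _corr_distance(matrix, on)
    order = np.argsort(ids)
    ids = ids[order]
    D = D[np.ix_(order, order)]
    if len(ids) < 2:
        raise ValueError("need >= 2 items to cluster")
    Z = hierarchy.average(squareform(D, checks=False))
    leaves = hierarchy.leaves_list(Z)
    return Z, [ids[i] for i in leaves]


def mds_embed(matrix: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on distance 1 - Pearson r.

    Coordinates are centered; reflections are fixed by requiring the first
    sample's coordinate to be nonnegative in every dimension.
    """
    n = matrix.shape[1]
    if n < dims + 1:
        raise ValueError(f"need >= dims+1 samples ({dims + 1}), got {n}")
    ids, D = _corr_distance(matrix, "samples")
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    pos = vals > max(vals[0], 0) * 1e-10
    avail = int(pos.sum())
    use = min(dims, avail)
    if use < dims:
        import warnings

        warnings.warn(f"mds_embed: rank {avail} < dims {dims}, returning {use} dims")
    coords = vecs[:, :use] * np.sqrt(vals[:use])
    for j in range(use):
        if coords[0, j] < 0:
            coords[:, j] = -coords[:, j]
    # undo the ID sort from _corr_distance back to column order
    back = {s: i for i, s in enumerate(ids)}
    coords = coords[[back[s] for s in matrix.columns]]
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"dim{j + 1}" for j in range(use)]
    )


def foldchange_concordance(a: pd.DataFrame, b: pd.DataFrame, labels):
    """Per-gene log2 fold changes (class 2 - class 1) on each platform.

    Returns (DataFrame with columns fc_a, fc_b; Pearson r between them).
    ``labels`` is a ClassLabels covering the samples of both matrices.
    """
    if not a.index.equals(b.index):
        raise ValueError("gene spaces must be aligned")

    def _fc(m):
        cls = labels.classes.reindex(m.columns)
        if cls.isna().any():
            raise ValueError("samples without class label")
        c1 = m.loc[:, (cls == 1).to_numpy()]
        c2 = m.loc[:, (cls == 2).to_numpy()]
        if c1.shape[1] == 0 or c2.shape[1] == 0:
            raise ValueError("a class is missing on one platform")
        return c2.mean(axis=1) - c1.mean(axis=1)

    fc = pd.DataFrame({"fc_a": _fc(a), "fc_b": _fc(b)})
    r = float(np.corrcoef(fc["fc_a"], fc["fc_b"])[0, 1])
    return fc, r


def most_variable_genes(matrix: pd.DataFrame, n: int):
    """Top n genes by across-sample variance; ties broken by gene ID."""
    if n > matrix.shape[0]:
        raise ValueError(f"n={n} exceeds number of genes ({matrix.shape[0]})")
    var = matrix.var(axis=1, ddof=1)
    ranked = sorted(var.index, key=lambda g: (-var[g], g))
    return list(ranked[:n])


@dataclass
class CentroidSet:
    """Named subtype signature: gene x subtype centroid matrix."""

    name: str
    centroids: pd.DataFrame

    def __post_init__(self):
        if self.centroids.shape[1] < 2:
            raise ValueError("need >= 2 subtypes")
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate centroid gene IDs")


def assign_subtypes(
    matrix: pd.DataFrame, centroids: CentroidSet, method: str = "spearman"
):
    """Nearest-centroid subtype call per sample.

    The matrix is per-gene median-centered over samples, restricted to the
    genes shared with the signature, and each sample is assigned the
    subtype with the highest Spearman (or Pearson) correlation.  Ties give
    an 'unassigned' flag.  Returns a DataFrame with the per-subtype
    correlations, the call and the flag.
    """
    shared = matrix.index.intersection(centroids.centroids.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with signature (need >= 10)")
    sub = matrix.loc[shared]
    centered = sub.sub(sub.median(axis=1), axis=0)
    C = centroids.centroids.loc[shared]

    names = list(C.columns)
    rows = []
    for s in matrix.columns:
        x = centered[s].to_numpy()
        if method == "spearman":
            cors = [spearmanr(x, C[k].to_numpy()).statistic for k in names]
        elif method == "pearson":
            cors = [float(np.corrcoef(x, C[k].to_numpy())[0, 1]) for k in names]
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        cors = np.asarray(cors, dtype=float)
        best = np.nanmax(cors)
        winners = [names[i] for i in np.flatnonzero(cors == best)]
        call = winners[0] if len(winners) == 1 else None
        rows.append(list(cors) + [call, len(winners) > 1])
    return pd.DataFrame(
        rows, index=matrix.columns, columns=names + ["subtype", "tied"]
    )


def agreement(labels_a, labels_b) -> float:
    """Percent of samples with matching assignments."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b).reindex(a.index)
    if len(a) == 0:
        raise ValueError("empty label vectors")
    return 100.0 * float((a == b).mean())
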