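"""Cross-platform correction methods: mean-centering, ComBat, DWD and XPN.

All four operate on a log2-scale gene x sample matrix with per-sample batch
labels (batch = platform throughout).  They differ in how much of the batch
structure they model:

* ``mean_center`` removes the per-gene per-batch mean — location only.
* ``combat`` is the parametric empirical-Bayes location/scale adjustment:
  per-gene per-batch shifts and scale factors are shrunk toward across-gene
  priors (normal for location, inverse-gamma for scale) before removal.
* ``dwd_correct`` finds the distance-weighted-discrimination direction
  separating the two batches and translates each batch along it to the
  grand-mean projection — a single global shift per batch.
* ``xpn`` fits a block model (gene clusters x sample clusters) per platform
  and replaces the platform-specific block parameters with sample-size
  weighted consensus values, keeping each sample's standardized residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans

__all__ = [
    "mean_center",
    "combat",
    "CombatModel",
    "dwd_correct",
    "DwdDirection",
    "xpn",
    "XpnModel",
]


# ---------------------------------------------------------------------------
# batch-label plumbing


def _batch_series(matrix: pd.DataFrame, batches) -> pd.Series:
    s = pd.Series(batches)
    missing = matrix.columns.difference(s.index)
    if len(missing):
        raise ValueError(f"samples without batch label: {list(missing[:5])}")
    s = s.loc[matrix.columns].astype(str)
    return s


def _batch_indices(labels: pd.Series) -> dict:
    return {b: np.flatnonzero((labels == b).to_numpy()) for b in sorted(labels.unique())}


# ---------------------------------------------------------------------------
# mean centering


def mean_center(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Subtract the within-batch gene mean; per-gene per-batch means become 0."""
    labels = _batch_series(matrix, batches)
    X = matrix.to_numpy(dtype=float).copy()
    for b, idx in _batch_indices(labels).items():
        if idx.size == 0:
            raise ValueError(f"batch {b!r} is empty")
        X[:, idx] -= X[:, idx].mean(axis=1, keepdims=True)
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# ComBat (parametric empirical Bayes)


@dataclass
class CombatModel:
    """Fitted ComBat parameters (location/scale EB adjustment)."""

    batches: list
    alpha: np.ndarray  # per-gene grand mean (weighted by batch size)
    sigma: np.ndarray  # per-gene pooled scale (sd)
    gamma_hat: pd.DataFrame  # per-gene per-batch location estimates
    delta2_hat: pd.DataFrame  # per-gene per-batch scale estimates (variance)
    gamma_star: pd.DataFrame  # posterior locations
    delta2_star: pd.DataFrame  # posterior variances
    hyper: pd.DataFrame  # per-batch gamma_bar, tau2_bar, lambda, theta
    iterations: dict  # per-batch iterations used
    converged: dict  # per-batch convergence flag


def combat(
    matrix: pd.DataFrame,
    batches,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Per gene g and batch i the standardized data Z get batch location
    gamma_gi and scale delta2_gi estimates which are shrunk toward
    across-gene moment-matched priors; the adjusted data are
    ``(sigma_g / delta*_gi) * (Z - gamma*_gi) + alpha_g``.
    """
    labels = _batch_series(matrix, batches)
    groups = _batch_indices(labels)
    if len(groups) < 2:
        raise ValueError("combat requires at least two batches")
    for b, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    G, N = matrix.shape
    if G < 25:
        raise ValueError("combat needs >= 25 genes for stable hyperparameters")

    X = matrix.to_numpy(dtype=float)
    batch_names = list(groups)
    n_i = np.array([groups[b].size for b in batch_names], dtype=float)

    # per-gene batch means and size-weighted grand mean
    M = np.stack([X[:, groups[b]].mean(axis=1) for b in batch_names], axis=1)
    alpha = M @ (n_i / N)
    resid = X.copy()
    for j, b in enumerate(batch_names):
        resid[:, groups[b]] -= M[:, [j]]
    sigma2 = (resid**2).sum(axis=1) / N
    sigma = np.sqrt(np.maximum(sigma2, 1e-16))

    Z = (X - alpha[:, None]) / sigma[:, None]

    gamma_hat = np.empty((G, len(batch_names)))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    hyper_rows = []
    iterations: dict = {}
    converged: dict = {}

    for j, b in enumerate(batch_names):
        idx = groups[b]
        Zb = Z[:, idx]
        n = idx.size
        g_hat = Zb.mean(axis=1)
        d2_hat = Zb.var(axis=1, ddof=1)
        gamma_hat[:, j] = g_hat
        delta2_hat[:, j] = d2_hat

        gamma_bar = g_hat.mean()
        tau2_bar = g_hat.var(ddof=1)
        V = d2_hat.mean()
        S2 = max(d2_hat.var(ddof=1), 1e-12)
        lam = (V**2 + 2.0 * S2) / S2
        theta = (V**3 + V * S2) / S2
        hyper_rows.append((gamma_bar, tau2_bar, lam, theta))

        sZ = Zb.sum(axis=1)
        sZ2 = (Zb**2).sum(axis=1)
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (n * tau2_bar * g_hat + d2_star * gamma_bar) / (
                n * tau2_bar + d2_star
            )
            sum2 = sZ2 - 2.0 * g_new * sZ + n * g_new**2
            d2_new = (theta + 0.5 * sum2) / (n / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_star)), np.max(np.abs(d2_new - d2_star))
            )
            g_star, d2_star = g_new, d2_new
            if change < tol:
                ok = True
                break
        if not ok:
            warnings.warn(f"combat: batch {b!r} did not converge in {max_iter} iters")
        gamma_star[:, j] = g_star
        delta2_star[:, j] = np.maximum(d2_star, 1e-16)
        iterations[b] = it
        converged[b] = ok

    Xstar = np.empty_like(X)
    for j, b in enumerate(batch_names):
        idx = groups[b]
        Xstar[:, idx] = (
            sigma[:, None]
            / np.sqrt(delta2_star[:, [j]])
            * (Z[:, idx] - gamma_star[:, [j]])
            + alpha[:, None]
        )

    gene_index = matrix.index
    model = CombatModel(
        batches=batch_names,
        alpha=alpha,
        sigma=sigma,
        gamma_hat=pd.DataFrame(gamma_hat, index=gene_index, columns=batch_names),
        delta2_hat=pd.DataFrame(delta2_hat, index=gene_index, columns=batch_names),
        gamma_star=pd.DataFrame(gamma_star, index=gene_index, columns=batch_names),
        delta2_star=pd.DataFrame(delta2_star, index=gene_index, columns=batch_names),
        hyper=pd.DataFrame(
            hyper_rows,
            index=batch_names,
            columns=["gamma_bar", "tau2_bar", "lambda", "theta"],
        ),
        iterations=iterations,
        converged=converged,
    )
    return pd.DataFrame(Xstar, index=gene_index, columns=matrix.columns), model


# ---------------------------------------------------------------------------
# DWD


@dataclass
class DwdDirection:
    """DWD separating direction and the batch projections it equalizes."""

    w: pd.Series  # unit direction over genes
    beta: float
    penalty: float
    batch_proj_before: dict
    batch_proj_after: dict
    objective: float = np.nan


def _dwd_objective(C: float):
    """Smooth DWD loss after exact elimination of the slack variables.

    For margin m_i = y_i (w.x_i + beta) the per-sample loss is 1/m for
    m >= 1/sqrt(C) and 2 sqrt(C) - C m otherwise; convex and C1.
    """
    thr = 1.0 / np.sqrt(C)

    def phi(m):
        out = 2.0 / thr - C * m
        hi = m >= thr
        out[hi] = 1.0 / m[hi]
        return out

    def dphi(m):
        out = np.full_like(m, -C)
        hi = m >= thr
        out[hi] = -1.0 / m[hi] ** 2
        return out

    return phi, dphi


def dwd_correct(matrix: pd.DataFrame, batches, penalty="auto"):
    """DWD batch adjustment: translate each batch along the DWD direction.

    Exactly two batches.  The direction solves
    min sum_i 1/r_i + C sum_i xi_i, r_i = y_i (w.x_i + beta) + xi_i,
    xi_i >= 0, ||w|| <= 1, computed in the span of the samples.  Each batch
    is then translated along w to the grand-mean projection, so both
    batch-mean projections agree afterwards (and identical batches are
    left unchanged).
    """
    labels = _batch_series(matrix, batches)
    groups = _batch_indices(labels)
    if len(groups) != 2:
        raise ValueError(f"dwd_correct requires exactly 2 batches, got {len(groups)}")
    for b, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    b1, b2 = list(groups)
    X = matrix.to_numpy(dtype=float)
    y = np.where((labels == b1).to_numpy(), 1.0, -1.0)

    # work in the span of the samples: X = U @ coords
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > max(s[0], 1.0) * 1e-12 if s.size else slice(0)
    U = U[:, keep]
    coords = (s[keep, None] * Vt[keep])  # r x n

    if penalty == "auto":
        A = coords[:, groups[b1]]
        B = coords[:, groups[b2]]
        diff = A[:, :, None] - B[:, None, :]
        dist = np.sqrt((diff**2).sum(axis=0))
        med = np.median(dist)
        if med <= 0:
            med = 1.0
        C = 100.0 / med**2
    else:
        C = float(penalty)
    phi, dphi = _dwd_objective(C)

    r = coords.shape[0]
    m1 = coords[:, groups[b1]].mean(axis=1)
    m2 = coords[:, groups[b2]].mean(axis=1)
    d0 = m1 - m2
    nrm = np.linalg.norm(d0)
    c0 = d0 / nrm if nrm > 0 else np.zeros(r)
    beta0 = -float(c0 @ (m1 + m2) / 2.0)

    def fun(z):
        c, beta = z[:r], z[r]
        m = y * (c @ coords + beta)
        val = phi(m).sum()
        g = dphi(m)
        grad_c = coords @ (g * y)
        grad_b = float((g * y).sum())
        return val, np.concatenate([grad_c, [grad_b]])

    cons = {
        "type": "ineq",
        "fun": lambda z: 1.0 - z[:r] @ z[:r],
        "jac": lambda z: np.concatenate([-2.0 * z[:r], [0.0]]),
    }
    z0 = np.concatenate([0.95 * c0, [beta0]])
    res = minimize(
        fun, z0, jac=True, method="SLSQP", constraints=[cons],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        res2 = minimize(
            fun, z0, jac=True, method="trust-constr",
            constraints=[
                {"type": "ineq", "fun": cons["fun"], "jac": lambda z: cons["jac"](z)[None, :]}
            ],
            options={"maxiter": 2000},
        )
        if res2.fun < res.fun:
            res = res2
        if not (res.success or res2.success):
            raise RuntimeError(f"DWD solver failed: {res.message}")
    c = res.x[:r]
    beta = float(res.x[r])
    nc = np.linalg.norm(c)
    if nc == 0:
        raise RuntimeError("DWD solver returned a zero direction")
    c = c / nc  # optimum lies on the unit sphere

    w = U @ c
    w = w / np.linalg.norm(w)
    proj = w @ X
    if proj[groups[b1]].mean() < 0:  # sign convention: batch 1 projects positive
        w, beta, proj = -w, -beta, -proj

    before = {b: float(proj[idx].mean()) for b, idx in groups.items()}
    grand = float(proj.mean())
    Xadj = X.copy()
    for b, idx in groups.items():
        # translate each batch so its mean projection matches the grand mean
        # projection: batches with equal means are left untouched
        Xadj[:, idx] -= (before[b] - grand) * w[:, None]
    proj_after = w @ Xadj
    after = {b: float(proj_after[idx].mean()) for b, idx in groups.items()}

    direction = DwdDirection(
        w=pd.Series(w, index=matrix.index),
        beta=beta,
        penalty=C,
        batch_proj_before=before,
        batch_proj_after=after,
        objective=float(res.fun),
    )
    return pd.DataFrame(Xadj, index=matrix.index, columns=matrix.columns), direction


# ---------------------------------------------------------------------------
# XPN


@dataclass
class XpnModel:
    """Parameters of the last XPN repetition plus per-repetition seeds."""

    K: int
    L: int
    reps: int
    seed: int
    rep_seeds: list = field(default_factory=list)
    gene_clusters: np.ndarray | None = None
    sample_clusters: np.ndarray | None = None
    A_consensus: np.ndarray | None = None
    b_consensus: np.ndarray | None = None
    c_consensus: np.ndarray | None = None
    sigma_consensus: np.ndarray | None = None


def _xpn_fit_platform(X, gene_cl, sample_cl, K, L, max_iter=30, tol=1e-6):
    """Alternating least squares for x_gi = A[gc(g), sc(i)] * b_g + c_g + eps.

    The per-gene sensitivity b_g is estimated with a unit-information
    prior centred at 1 (ridge lambda = sigma_g^2 / n).  This keeps b_g
    bounded when a cluster's block profile is flat (pure least squares
    divides by a near-zero profile variance there) and pins the scale
    gauge of the (A, b) factorization, so the per-platform parameters are
    on a common scale and can be averaged into a consensus.
    """
    G, n = X.shape
    b = np.ones(G)
    c = np.zeros(G)
    A = np.zeros((K, L))
    sigma2 = np.maximum(X.var(axis=1), 1e-12)
    # column-cluster membership and sizes within this platform
    col_mask = [np.flatnonzero(sample_cl == l) for l in range(L)]
    n_l = np.array([m.size for m in col_mask], dtype=float)
    gene_mask = [np.flatnonzero(gene_cl == k) for k in range(K)]

    prev_fit = None
    for _ in range(max_iter):
        # A update given b, c
        R = X - c[:, None]
        bR_row = b[:, None] * R  # G x n
        for k in range(K):
            gm = gene_mask[k]
            if gm.size == 0:
                continue
            sb2 = float((b[gm] ** 2).sum())
            for l in range(L):
                cm = col_mask[l]
                if cm.size == 0 or sb2 <= 1e-12:
                    A[k, l] = 0.0
                    continue
                A[k, l] = bR_row[np.ix_(gm, cm)].sum() / (sb2 * cm.size)
        # b, c update given A: ridge regression of each gene on its block
        # profile, shrinking b toward 1 with unit-information strength
        T = A[gene_cl][:, sample_cl]  # G x n predictor per cell
        t_mean = T.mean(axis=1)
        x_mean = X.mean(axis=1)
        cov = ((T - t_mean[:, None]) * (X - x_mean[:, None])).mean(axis=1)
        var = ((T - t_mean[:, None]) ** 2).mean(axis=1)
        lam = np.maximum(sigma2 / n, 1e-12)
        b = (cov + lam) / (var + lam)
        c = x_mean - b * t_mean
        fit = A[gene_cl][:, sample_cl] * b[:, None] + c[:, None]
        sigma2 = np.maximum(((X - fit) ** 2).mean(axis=1), 1e-12)
        if prev_fit is not None and np.max(np.abs(fit - prev_fit)) < tol:
            prev_fit = fit
            break
        prev_fit = fit

    resid = X - prev_fit
    sigma = np.sqrt((resid**2).mean(axis=1))
    floored = sigma < 1e-8
    if floored.any():
        warnings.warn(f"xpn: {int(floored.sum())} zero-variance genes, sigma floored")
        sigma = np.maximum(sigma, 1e-8)
    return A, b, c, sigma, resid / sigma[:, None]


def xpn(
    a: pd.DataFrame,
    b: pd.DataFrame,
    K: int = 25,
    L: int = 5,
    reps: int = 30,
    seed: int = 0,
    max_als_iter: int = 30,
):
    """Cross-platform normalization via the clustered block model.

    Per repetition, genes are k-means clustered into K row clusters and the
    pooled samples into L column clusters; each platform's block parameters
    (A, b, c, sigma) are fitted by alternating least squares and replaced by
    sample-size-weighted consensus values; every sample is reconstructed
    with the consensus parameters plus its own standardized residual.  The
    output is the mean over repetitions.
    """
    if not a.index.equals(b.index):
        raise ValueError("gene spaces must be aligned before xpn")
    G = a.shape[0]
    n1, n2 = a.shape[1], b.shape[1]
    if K > G:
        raise ValueError(f"K={K} exceeds number of genes ({G})")
    if L > min(n1, n2):
        raise ValueError(f"L={L} exceeds samples on one platform ({n1}, {n2})")

    Xa = a.to_numpy(dtype=float)
    Xb = b.to_numpy(dtype=float)
    pooled = np.hstack([Xa, Xb])

    # gene clustering view: per-platform gene standardization removes
    # platform location/scale so row clusters reflect co-expression
    def _std_rows(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        return (M - mu) / np.maximum(sd, 1e-8)

    gene_view = np.hstack([_std_rows(Xa), _std_rows(Xb)])
    # per-platform gene standardization also feeds the sample clustering:
    # raw pooled columns would cluster by platform (gene-wise offsets are a
    # shared column pattern), hiding the biology the column clusters exist
    # to capture
    col_view = gene_view - gene_view.mean(axis=0, keepdims=True)
    col_sd = np.maximum(col_view.std(axis=0, keepdims=True), 1e-8)
    col_view = col_view / col_sd

    rng = np.random.default_rng(seed)
    rep_seeds = [int(x) for x in rng.integers(0, 2**31 - 1, size=reps)]

    acc = np.zeros_like(pooled)
    model = XpnModel(K=K, L=L, reps=reps, seed=seed, rep_seeds=rep_seeds)
    for rs in rep_seeds:
        gene_cl = KMeans(n_clusters=K, n_init=2, random_state=rs).fit_predict(gene_view)
        sample_cl = KMeans(
            n_clusters=L, n_init=2, random_state=rs + 1
        ).fit_predict(col_view.T)
        sc_a, sc_b = sample_cl[:n1], sample_cl[n1:]

        A1, b1, c1, s1, z1 = _xpn_fit_platform(Xa, gene_cl, sc_a, K, L, max_als_iter)
        A2, b2, c2, s2, z2 = _xpn_fit_platform(Xb, gene_cl, sc_b, K, L, max_als_iter)

        # sample-size-weighted consensus; per-column-cluster weights for A
        w1 = np.array([(sc_a == l).sum() for l in range(L)], dtype=float)
        w2 = np.array([(sc_b == l).sum() for l in range(L)], dtype=float)
        tot = np.maximum(w1 + w2, 1.0)
        Ac = (A1 * w1[None, :] + A2 * w2[None, :]) / tot[None, :]
        bc = (n1 * b1 + n2 * b2) / (n1 + n2)
        cc = (n1 * c1 + n2 * c2) / (n1 + n2)
        sc_ = (n1 * s1 + n2 * s2) / (n1 + n2)

        rec1 = Ac[gene_cl][:, sc_a] * bc[:, None] + cc[:, None] + sc_[:, None] * z1
        rec2 = Ac[gene_cl][:, sc_b] * bc[:, None] + cc[:, None] + sc_[:, None] * z2
        acc[:, :n1] += rec1
        acc[:, n1:] += rec2
        model.gene_clusters = gene_cl
        model.sample_clusters = sample_cl
        model.A_consensus = Ac
        model.b_consensus = bc
        model.c_consensus = cc
        model.sigma_consensus = sc_

    acc /= reps
    combined = pd.DataFrame(
        acc, index=a.index, columns=list(a.columns) + list(b.columns)
    )
    return combined, model
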