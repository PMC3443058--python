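"""Per-gene nested random-effects variance decomposition.

The measurement model for gene expression X_ijkl on the log2 scale is

    X_ijkl = mu + A_i + B_ij + C_ijk + e_ijkl

with A the biological-sample effect, B the platform effect nested in
sample, C the lab effect nested in platform and e the replicate/residual
term (a replicate is hybridized once, so the replicate effect and the
measurement error are not separately identifiable and are reported as one
residual component).  Estimation is per gene, either by expected mean
squares on a balanced design (``anova``) or by REML (``reml``).

On a balanced design the restricted likelihood separates into independent
gamma likelihoods for the stratum variances

    lam_within = s2_res
    lam_lab    = s2_res + v*s2_lab
    lam_plat   = s2_res + v*s2_lab + u*v*s2_platform
    lam_sample = s2_res + v*s2_lab + u*v*s2_platform + t*u*v*s2_sample

so constrained REML is an isotonic (df-weighted PAVA) fit of the stratum
mean squares; when the mean squares are already ordered (interior
solution) REML and ANOVA coincide.  Unbalanced designs use a generic
per-gene REML on the full covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "NestedDesign",
    "VarianceComponents",
    "fit_nested_components",
    "pool_fractions",
    "LEVELS",
]

LEVELS = ["sample", "platform", "lab", "residual"]
_COLS = [f"sigma2_{lv}" for lv in LEVELS]


@dataclass
class NestedDesign:
    """Per-sample nested factors: sample_type > platform > lab > replicate."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sample_type", "platform", "lab", "replicate")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns {missing}")
        self.table = self.table.astype(str)

    @property
    def balanced(self) -> bool:
        t = self.table
        plats = t.groupby("sample_type")["platform"].nunique()
        labs = t.groupby(["sample_type", "platform"])["lab"].nunique()
        reps = t.groupby(["sample_type", "platform", "lab"]).size()
        return plats.nunique() == 1 and labs.nunique() == 1 and reps.nunique() == 1

    def shape(self):
        """(s, t, u, v) branch counts; only meaningful when balanced."""
        t = self.table
        s = t["sample_type"].nunique()
        tt = t.groupby("sample_type")["platform"].nunique().iloc[0]
        u = t.groupby(["sample_type", "platform"])["lab"].nunique().iloc[0]
        v = int(t.groupby(["sample_type", "platform", "lab"]).size().iloc[0])
        return s, tt, u, v


@dataclass
class VarianceComponents:
    """Per-gene variance components with the fit method and pooling helpers."""

    table: pd.DataFrame  # columns sigma2_sample/platform/lab/residual, converged
    method: str

    def totals(self) -> pd.Series:
        return self.table[_COLS].sum(axis=1)


def _pava_decreasing(ms: np.ndarray, df: np.ndarray) -> np.ndarray:
    """df-weighted pool-adjacent-violators enforcing ms[0] >= ms[1] >= ...

    ms rows are per-gene stratum mean squares ordered sample, platform,
    lab, within; the pooled value of a merged block is sum(SS)/sum(df),
    which maximizes the restricted likelihood under the order constraint.
    """
    G, H = ms.shape
    out = ms.copy()
    # tiny H (=4): simple stack-based PAVA per gene, vectorized over genes
    for g in range(G):
        vals = list(out[g])
        wts = list(df.astype(float))
        blocks = []  # (value, weight)
        for v, w in zip(vals, wts):
            blocks.append([v, w])
            while len(blocks) > 1 and blocks[-2][0] < blocks[-1][0]:
                v2, w2 = blocks.pop()
                v1, w1 = blocks.pop()
                blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
        flat = []
        for v, w in blocks:
            # expand back: weight w covers w/df units... reconstruct by count
            flat.append((v, w))
        # expand by consuming original dfs in order
        res = np.empty(H)
        bi = 0
        acc = flat[0][1]
        for h in range(H):
            res[h] = flat[bi][0]
            acc -= df[h]
            if acc <= 1e-9 and bi + 1 < len(flat):
                bi += 1
                acc = flat[bi][1]
        out[g] = res
    return out


def _fit_balanced(values: np.ndarray, design: NestedDesign, order, method: str):
    s, t, u, v = design.shape()
    Y = values[:, order].reshape(values.shape[0], s, t, u, v)
    m_lab = Y.mean(axis=4)
    m_plat = m_lab.mean(axis=3)
    m_samp = m_plat.mean(axis=2)
    grand = m_samp.mean(axis=1)

    df = np.array([s - 1, s * (t - 1), s * t * (u - 1), s * t * u * (v - 1)])
    if (df == 0).any():
        raise ValueError(
            "degenerate design: a stratum has zero degrees of freedom "
            f"(s,t,u,v = {(s, t, u, v)})"
        )
    ss_samp = t * u * v * ((m_samp - grand[:, None]) ** 2).sum(axis=1)
    ss_plat = u * v * ((m_plat - m_samp[..., None]) ** 2).sum(axis=(1, 2))
    ss_lab = v * ((m_lab - m_plat[..., None]) ** 2).sum(axis=(1, 2, 3))
    ss_within = ((Y - m_lab[..., None]) ** 2).sum(axis=(1, 2, 3, 4))
    MS = np.stack([ss_samp, ss_plat, ss_lab, ss_within], axis=1) / df[None, :]

    if method == "anova":
        lam = MS
    else:  # reml: isotonic constrained maximum of the stratum likelihoods
        lam = _pava_decreasing(MS, df)

    s2_res = lam[:, 3]
    s2_lab = (lam[:, 2] - lam[:, 3]) / v
    s2_plat = (lam[:, 1] - lam[:, 2]) / (u * v)
    s2_samp = (lam[:, 0] - lam[:, 1]) / (t * u * v)
    comps = np.stack([s2_samp, s2_plat, s2_lab, s2_res], axis=1)
    comps = np.maximum(comps, 0.0)  # anova EMS can go negative; truncate
    return comps, np.ones(values.shape[0], dtype=bool)


def _incidence(design: NestedDesign, columns):
    t = design.table.loc[list(columns)]
    za = pd.get_dummies(t["sample_type"]).to_numpy(float)
    zb = pd.get_dummies(
        t["sample_type"] + "|" + t["platform"]
    ).to_numpy(float)
    zc = pd.get_dummies(
        t["sample_type"] + "|" + t["platform"] + "|" + t["lab"]
    ).to_numpy(float)
    return za, zb, zc


def _reml_loglik(logv, y, mats):
    n = y.size
    V = np.exp(logv[3]) * np.eye(n)
    for q, Z in enumerate(mats):
        V += np.exp(logv[q]) * (Z @ Z.T)
    try:
        Lc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(Lc)).sum()
    Vi_y = np.linalg.solve(V, y)
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    xvx = ones @ Vi_1
    mu = (ones @ Vi_y) / xvx
    r = y - mu
    Vi_r = Vi_y - mu * Vi_1
    return 0.5 * (logdet + np.log(xvx) + r @ Vi_r)


def _fit_unbalanced(values: np.ndarray, design: NestedDesign, columns):
    mats = _incidence(design, columns)
    G = values.shape[0]
    comps = np.zeros((G, 4))
    converged = np.zeros(G, dtype=bool)
    for g in range(G):
        y = values[g]
        vy = y.var()
        if vy <= 0:
            converged[g] = True
            continue
        best = None
        for start in (np.log(np.full(4, vy / 4)), np.log([vy, vy / 10, vy / 10, vy / 2])):
            res = minimize(
                _reml_loglik, start, args=(y, mats), method="L-BFGS-B",
                bounds=[(np.log(vy) - 25.0, np.log(vy) + 6.0)] * 4,
            )
            if best is None or res.fun < best.fun:
                best = res
        est = np.exp(best.x)
        est[est < vy * 1e-8] = 0.0  # components driven to the boundary
        comps[g] = est
        converged[g] = bool(best.success)
    return comps, converged


def fit_nested_components(
    matrix: pd.DataFrame, design: NestedDesign, method: str = "reml"
) -> VarianceComponents:
    """Estimate per-gene (sample, platform, lab, residual) variances."""
    if method not in ("reml", "anova"):
        raise ValueError("method must be 'reml' or 'anova'")
    missing = matrix.columns.difference(design.table.index)
    if len(missing):
        raise ValueError(f"design does not cover samples {list(missing[:5])}")
    balanced = design.balanced
    if method == "anova" and not balanced:
        raise ValueError("anova requires a balanced design; use method='reml'")

    values = matrix.to_numpy(dtype=float)
    if balanced:
        t = design.table.loc[matrix.columns]
        order = np.lexsort(
            (t["replicate"].to_numpy(), t["lab"].to_numpy(),
             t["platform"].to_numpy(), t["sample_type"].to_numpy())
        )
        comps, converged = _fit_balanced(values, design, order, method)
    else:
        comps, converged = _fit_unbalanced(values, design, matrix.columns)

    table = pd.DataFrame(comps, index=matrix.index, columns=_COLS)
    table["converged"] = converged
    return VarianceComponents(table=table, method=method)


def pool_fractions(components: VarianceComponents, pooling: str = "sums"):
    """Pooled per-level variance fractions across genes.

    ``sums`` (default) divides the summed components by the summed totals —
    stable when many genes have tiny totals; ``mean`` averages the per-gene
    fraction rows instead.  Returns (pooled Series, per-gene fraction table).
    """
    comp = components.table[_COLS]
    totals = comp.sum(axis=1)
    if not (totals > 0).any():
        raise ValueError("all genes have zero total variance")
    per_gene = comp.div(totals, axis=0)
    per_gene = per_gene.where(totals > 0)
    if pooling == "sums":
        pooled = comp.sum(axis=0) / totals.sum()
    elif pooling == "mean":
        pooled = per_gene.mean(axis=0)
        pooled = pooled / pooled.sum()
    else:
        raise ValueError("pooling must be 'sums' or 'mean'")
    pooled.index = LEVELS
    per_gene.columns = LEVELS
    return pooled, per_gene
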