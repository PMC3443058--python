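"""Synthetic-data generators with the statistical structure the pipeline
assumes, so every stage is testable without array downloads.

Two designs are emulated:

* the MAQC-style nested design — four reference-RNA sample types
  (A = 100% UHRR, B = 100% HBRR, C = 75/25, D = 25/75 titrations) measured
  on two platforms, several labs per platform and several replicate
  hybridizations per lab, with independent log2-scale random effects at
  every level and optional gene-wise cross-platform bias (additive offset
  plus multiplicative sensitivity slope);

* a paired clinical design — patients with baseline and three-month
  samples assayed on two single-channel platforms, a treatment effect on a
  subset of genes, and the same gene-wise platform bias model, plus
  detection p-values.

Both generators are fully deterministic given their seed and return a
truth record holding every drawn effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variance import NestedDesign

__all__ = ["MaqcSimSpec", "ClinicalSimSpec", "simulate_maqc", "simulate_clinical"]


@dataclass
class MaqcSimSpec:
    """Study conditions for the MAQC-like nested simulation.

    Variance components are on the log2 scale.  ``titration`` derives the
    C and D sample-type effects from the A and B effects by linear-scale
    RNA mixing (75/25 and 25/75); with it off, all four effects are drawn
    i.i.d.  ``platform_offset_sd`` and ``platform_slope_sigma`` add
    gene-wise cross-platform bias (offset ~ N(0, sd^2), sensitivity slope
    ~ LogNormal(0, sigma^2)) to every platform after the first.
    """

    n_genes: int = 1000
    sample_types: tuple = ("A", "B", "C", "D")
    n_platforms: int = 2
    n_labs: int = 3
    n_reps: int = 5
    var_sample: float = 4.0
    var_platform: float = 1.0
    var_lab: float = 0.25
    var_residual: float = 0.04
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    titration: bool = True
    mix_fractions: tuple = (0.75, 0.25)  # C = f*A + (1-f)*B ; D mirrored
    platform_offset_sd: float = 0.0
    platform_slope_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("var_sample", "var_platform", "var_lab", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_genes, self.n_platforms, self.n_labs, self.n_reps) < 1:
            raise ValueError("all counts must be >= 1")
        if self.titration and len(self.sample_types) != 4:
            raise ValueError("titration mixing requires the 4 MAQC sample types")


def _mix_log2(a_eff, b_eff, frac):
    return np.log2(frac * 2.0**a_eff + (1.0 - frac) * 2.0**b_eff)


def simulate_maqc(spec: MaqcSimSpec):
    """Draw a MAQC-like nested dataset.

    Returns (ExpressionMatrix DataFrame, NestedDesign, truth dict).  The
    truth dict stores every drawn effect plus ``realized`` per-level
    variances (the quantities the nested ANOVA/REML estimates), computed
    with the same within-branch centering as the estimator's strata.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    s = len(spec.sample_types)
    t, u, v = spec.n_platforms, spec.n_labs, spec.n_reps
    sdA = np.sqrt(spec.var_sample)

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    if spec.titration:
        a = np.empty((G, s))
        a[:, 0] = rng.normal(0.0, sdA, size=G)  # A
        a[:, 1] = rng.normal(0.0, sdA, size=G)  # B
        f = spec.mix_fractions[0]
        a[:, 2] = _mix_log2(a[:, 0], a[:, 1], f)  # C
        a[:, 3] = _mix_log2(a[:, 0], a[:, 1], 1.0 - f)  # D
    else:
        a = rng.normal(0.0, sdA, size=(G, s))

    B = rng.normal(0.0, np.sqrt(spec.var_platform), size=(G, s, t))
    Cf = rng.normal(0.0, np.sqrt(spec.var_lab), size=(G, s, t, u))
    E = rng.normal(0.0, np.sqrt(spec.var_residual), size=(G, s, t, u, v))

    offsets = np.zeros((G, t))
    slopes = np.ones((G, t))
    if spec.platform_offset_sd > 0:
        offsets[:, 1:] = rng.normal(
            0.0, spec.platform_offset_sd, size=(G, t - 1)
        )
    if spec.platform_slope_sigma > 0:
        slopes[:, 1:] = rng.lognormal(
            0.0, spec.platform_slope_sigma, size=(G, t - 1)
        )

    signal = mu[:, None] + a  # G x s biological level
    X = (
        slopes[:, None, :, None, None] * signal[:, :, None, None, None]
        + offsets[:, None, :, None, None]
        + B[:, :, :, None, None]
        + Cf[:, :, :, :, None]
        + E
    )

    cols, rows = [], []
    for si, st_ in enumerate(spec.sample_types):
        for pj in range(t):
            for lk in range(u):
                for rl in range(v):
                    cols.append(f"{st_}_P{pj + 1}_L{lk + 1}_R{rl + 1}")
                    rows.append((st_, f"P{pj + 1}", f"L{lk + 1}", f"R{rl + 1}"))
    matrix = pd.DataFrame(
        X.reshape(G, s * t * u * v),
        index=[f"G{i:05d}" for i in range(G)],
        columns=cols,
    )
    design = NestedDesign(
        pd.DataFrame(
            rows,
            index=pd.Index(cols, name="sample_id"),
            columns=["sample_type", "platform", "lab", "replicate"],
        )
    )

    realized = {
        "sample": float(np.mean(a.var(axis=1, ddof=1))),
        "platform": float(
            np.sum((B - B.mean(axis=2, keepdims=True)) ** 2) / (G * s * (t - 1))
        )
        if t > 1
        else 0.0,
        "lab": float(
            np.sum((Cf - Cf.mean(axis=3, keepdims=True)) ** 2) / (G * s * t * (u - 1))
        )
        if u > 1
        else 0.0,
        "residual": float(
            np.sum((E - E.mean(axis=4, keepdims=True)) ** 2)
            / (G * s * t * u * (v - 1))
        )
        if v > 1
        else 0.0,
    }
    truth = {
        "mu": mu,
        "sample_effects": a,
        "platform_effects": B,
        "lab_effects": Cf,
        "residuals": E,
        "offsets": offsets,
        "slopes": slopes,
        "realized": realized,
        "spec": spec,
    }
    return matrix, design, truth


@dataclass
class ClinicalSimSpec:
    """Study conditions for the paired two-platform clinical simulation.

    Each platform assays ``n_pairs`` patients at baseline and three months;
    ``n_shared`` of them are assayed on both platforms.  A fraction of
    genes carries a treatment effect with log2 magnitude
    ~ LogNormal(log(effect_median), effect_sigma^2) and random sign.
    Platform 2 measures slope_g * signal + offset_g with
    slope ~ LogNormal(0, slope_sigma^2) and offset ~ N(0, offset_sd^2) —
    bias mean-centering cannot fully remove but ComBat/XPN shrink.
    """

    n_genes: int = 2000
    n_pairs: int = 24
    n_shared: int = 0
    frac_affected: float = 0.15
    effect_median: float = 1.0
    effect_sigma: float = 0.5
    patient_sd: float = 0.5
    noise_sd: float = 0.25
    offset_sd: float = 1.0
    slope_sigma: float = 0.2
    silent_fraction: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must be in [0, 1]")
        if self.n_pairs < 2:
            raise ValueError("need >= 2 patient pairs")
        if self.n_shared > self.n_pairs:
            raise ValueError("n_shared cannot exceed n_pairs")


def simulate_clinical(spec: ClinicalSimSpec):
    """Draw the paired clinical two-platform dataset.

    Returns (expr dict, detect dict, design DataFrame, truth dict) where
    expr/detect map platform name ('P1', 'P2') to matrices and the design
    has columns patient, platform, timepoint, class (1 = baseline,
    2 = three-month), pair_id.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)], name="gene_id")

    n_total = 2 * spec.n_pairs - spec.n_shared
    patients = [f"pt{i + 1:02d}" for i in range(n_total)]
    pts1 = patients[: spec.n_pairs]
    pts2 = patients[spec.n_pairs - spec.n_shared :]

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    n_aff = int(round(spec.frac_affected * G))
    affected_idx = rng.choice(G, size=n_aff, replace=False)
    effects = np.zeros(G)
    mag = rng.lognormal(np.log(spec.effect_median), spec.effect_sigma, size=n_aff)
    sign = rng.choice([-1.0, 1.0], size=n_aff)
    effects[affected_idx] = sign * mag

    baseline = {
        p: mu + rng.normal(0.0, spec.patient_sd, size=G) for p in patients
    }
    offsets = rng.normal(0.0, spec.offset_sd, size=G)
    slopes = rng.lognormal(0.0, spec.slope_sigma, size=G)
    silent = np.zeros(G, dtype=bool)
    n_silent = int(round(spec.silent_fraction * G))
    silent[rng.choice(G, size=n_silent, replace=False)] = True

    expr, detect, rows = {}, {}, []
    for platform, pts in (("P1", pts1), ("P2", pts2)):
        cols, data, pvals = [], [], []
        for p in pts:
            for tp, cls in (("baseline", 1), ("3month", 2)):
                signal = baseline[p] + (effects if cls == 2 else 0.0)
                if platform == "P2":
                    meas = slopes * signal + offsets
                else:
                    meas = signal.copy()
                meas = meas + rng.normal(0.0, spec.noise_sd, size=G)
                pv = np.where(
                    silent,
                    rng.uniform(0.2, 1.0, size=G),
                    rng.uniform(0.0, 0.01, size=G),
                )
                col = f"{platform}_{p}_{tp}"
                cols.append(col)
                data.append(meas)
                pvals.append(pv)
                rows.append((col, p, platform, tp, cls, p))
        expr[platform] = pd.DataFrame(
            np.column_stack(data), index=gene_ids, columns=cols
        )
        detect[platform] = pd.DataFrame(
            np.column_stack(pvals), index=gene_ids, columns=cols
        )

    design = pd.DataFrame(
        rows,
        columns=["sample_id", "patient", "platform", "timepoint", "class", "pair_id"],
    ).set_index("sample_id")

    truth = {
        "mu": mu,
        "effects": effects,
        "affected_genes": gene_ids[np.sort(affected_idx)].tolist(),
        "offsets": offsets,
        "slopes": slopes,
        "silent_genes": gene_ids[silent].tolist(),
        "patients": {"P1": pts1, "P2": pts2},
        "baseline_profiles": baseline,
        "spec": spec,
    }
    return expr, detect, design, truth
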