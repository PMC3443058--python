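"""End-to-end orchestration: simulate (or load) -> preprocess -> correct ->
variance decomposition / differential expression / evaluation, driven by a
config mapping, with a machine-readable report.

The report holds only numbers the stages computed plus provenance
(config, seeds); it is written atomically and is byte-identical across
reruns with the same config and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correction, diffexp, evaluation, io, preprocess, variance
from .simulate import ClinicalSimSpec, MaqcSimSpec, simulate_clinical, simulate_maqc

__all__ = ["run_pipeline", "compare_states", "load_config"]

log = logging.getLogger("crossnorm")

DEFAULT_CORRECTIONS = ["mean_center", "dwd", "combat"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_report(report: dict, outdir: Path) -> Path:
    path = outdir / "report.json"
    tmp = outdir / "report.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    os.replace(tmp, path)
    return path


def _apply_correction(method: str, matrix, batches, seed: int):
    if method == "mean_center":
        return correction.mean_center(matrix, batches)
    if method == "combat":
        corrected, _ = correction.combat(matrix, batches)
        return corrected
    if method == "dwd":
        corrected, _ = correction.dwd_correct(matrix, batches)
        return corrected
    raise ValueError(f"unknown correction method {method!r}")


def _variance_block(states: dict, design, method: str) -> dict:
    block = {}
    for name, matrix in states.items():
        comps = variance.fit_nested_components(matrix, design, method=method)
        pooled, _ = variance.pool_fractions(comps)
        block[name] = {lv: float(pooled[lv]) for lv in variance.LEVELS}
    return block


def _run_maqc(config: dict, outdir: Path, seed: int) -> dict:
    stages = config.get("stages", {})
    spec_kw = dict(config.get("simulation", {}).get("spec", {}))
    spec_kw.setdefault("seed", seed)
    spec = MaqcSimSpec(**spec_kw)
    t0 = time.perf_counter()
    matrix, design, truth = simulate_maqc(spec)
    log.info("simulate_maqc: %.1fs", time.perf_counter() - t0)
    io.write_matrix(matrix, outdir / "maqc_raw.tsv")
    io.write_design(design.table, outdir / "maqc_design.tsv")

    platform = design.table["platform"]
    states = {"raw": matrix}
    base = matrix
    if stages.get("quantile", True):
        # comparison state: pooled across platforms.  Forcing a common
        # intensity distribution removes the distributional part of the
        # platform bias; per-platform normalization cannot touch any
        # cross-platform difference and would leave this state at (or
        # above) the raw inter-platform fraction.
        states["quantile"] = preprocess.quantile_normalize(matrix)
        # correction input: normalized within each platform separately
        # (the workflow order: per-platform preprocessing, then correction)
        base = matrix.copy()
        for p in sorted(platform.unique()):
            cols = platform.index[platform == p]
            base[cols] = preprocess.quantile_normalize(matrix[cols])
    for method in stages.get("corrections", DEFAULT_CORRECTIONS):
        t0 = time.perf_counter()
        states[method] = _apply_correction(method, base, platform, seed)
        log.info("correction %s: %.1fs", method, time.perf_counter() - t0)
        io.write_matrix(states[method], outdir / f"maqc_{method}.tsv")

    report: dict = {"dataset": "maqc", "states": sorted(states)}
    if stages.get("variance", True):
        report["variance"] = _variance_block(
            states, design, stages.get("variance_method", "reml")
        )
    if stages.get("diffexp", False):
        de = {}
        labels = diffexp.ClassLabels(
            pd.Series(
                np.where(design.table["sample_type"] == "A", 1, 2),
                index=design.table.index,
            )
        )
        sam_cfg = stages.get("sam", {})
        state = sam_cfg.get("state", "combat")
        top = int(sam_cfg.get("top", 100))
        m = states[state]
        ab = design.table["sample_type"].isin(["A", "B"])
        lists = {}
        for scope, cols in (
            ("P1", ab & (platform == "P1")),
            ("P2", ab & (platform == "P2")),
            ("combined", ab),
        ):
            sub = m.loc[:, cols.to_numpy()]
            res = diffexp.sam_fdr(
                sub,
                labels.for_columns(sub.columns),
                s0=sam_cfg.get("s0", "auto"),
                n_perm=int(sam_cfg.get("n_perm", 100)),
                seed=seed,
            )
            lists[scope] = diffexp.top_n(res, top)
        de["top_n"] = top
        de["overlap_P1_P2_pct"] = diffexp.overlap(lists["P1"], lists["P2"], top)[1]
        de["overlap_combined_P1_pct"] = diffexp.overlap(
            lists["combined"], lists["P1"], top
        )[1]
        report["diffexp"] = de
    if stages.get("evaluation", False):
        corr = evaluation.pairwise_correlation(states.get("combat", base))
        cross = corr.to_numpy()[
            np.ix_(
                (platform == "P1").to_numpy(), (platform == "P2").to_numpy()
            )
        ]
        report["evaluation"] = {"mean_cross_platform_r": float(np.mean(cross))}
    report["truth_realized_variances"] = truth["realized"]
    return report


def _run_clinical(config: dict, outdir: Path, seed: int) -> dict:
    stages = config.get("stages", {})
    spec_kw = dict(config.get("simulation", {}).get("spec", {}))
    spec_kw.setdefault("seed", seed)
    spec = ClinicalSimSpec(**spec_kw)
    expr, detect, design, truth = simulate_clinical(spec)

    filt = stages.get("detection_filter", {"alpha": 0.05, "margin": 3})
    mats = {}
    for p in expr:
        m = expr[p]
        if filt:
            m = preprocess.detection_filter(
                m, detect[p], alpha=filt.get("alpha", 0.05), margin=filt.get("margin", 3)
            )
        if stages.get("quantile", True):
            m = preprocess.quantile_normalize(m)
        mats[p] = m
    from .annotation import align_gene_space

    a, b = align_gene_space(mats["P1"], mats["P2"])
    io.write_design(design, outdir / "clinical_design.tsv")

    labels = diffexp.ClassLabels(design["class"], design["pair_id"])
    fc_raw, r_raw = evaluation.foldchange_concordance(a, b, labels)
    report: dict = {
        "dataset": "clinical",
        "n_genes_after_filter": int(a.shape[0]),
        "fc_concordance": {"uncorrected": r_raw},
    }

    combined = pd.concat([a, b], axis=1)
    platform = design["platform"].loc[combined.columns]
    states = {"uncorrected": combined}
    for method in stages.get("corrections", ["combat", "xpn"]):
        if method == "xpn":
            xp_cfg = stages.get("xpn", {})
            corrected, _ = correction.xpn(
                a,
                b,
                K=int(xp_cfg.get("K", 25)),
                L=int(xp_cfg.get("L", 5)),
                reps=int(xp_cfg.get("reps", 30)),
                seed=seed,
            )
        else:
            corrected = _apply_correction(method, combined, platform, seed)
        states[method] = corrected
        io.write_matrix(corrected, outdir / f"clinical_{method}.tsv")
        ca = corrected[a.columns]
        cb = corrected[b.columns]
        _, r = evaluation.foldchange_concordance(ca, cb, labels)
        report["fc_concordance"][method] = r

    if stages.get("diffexp", True):
        sam_cfg = stages.get("sam", {})
        state = sam_cfg.get("state", "xpn" if "xpn" in states else "combat")
        res = diffexp.sam_fdr(
            states.get(state, combined),
            labels.for_columns(combined.columns),
            s0=sam_cfg.get("s0", "auto"),
            n_perm=int(sam_cfg.get("n_perm", 100)),
            seed=seed,
        )
        target_fdr = float(sam_cfg.get("target_fdr", 0.05))
        tab = res.fdr_table
        ok = tab[tab["fdr"] <= target_fdr]
        n_called = int(ok["n_called"].max()) if len(ok) else 0
        report["diffexp"] = {
            "state": state,
            "s0": res.s0,
            "target_fdr": target_fdr,
            "n_called_at_target_fdr": n_called,
        }
    return report


def run_pipeline(config: dict, outdir=None, seed: int | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    outdir = Path(outdir if outdir is not None else config.get("outdir", "crossnorm_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    sim = config.get("simulation")
    if sim is None:
        raise ValueError("config must contain a 'simulation' block (or input paths)")
    kind = sim.get("kind", "maqc")
    try:
        if kind == "maqc":
            report = _run_maqc(config, outdir, seed)
        elif kind == "clinical":
            report = _run_clinical(config, outdir, seed)
        else:
            raise ValueError(f"unknown simulation kind {kind!r}")
    except Exception:
        (outdir / "FAILED").write_text("pipeline stage failed\n")
        raise
    report["provenance"] = {"seed": seed, "config": config, "schema": 1}
    _write_report(report, outdir)
    return report


def compare_states(report: dict) -> pd.DataFrame:
    """Rank correction states by inter-platform variance fraction.

    Flags any state whose inter-sample fraction drops more than 50%
    relative to the raw state (the DWD pathology).
    """
    block = report.get("variance")
    if not block:
        raise ValueError("report has no variance block")
    if len(block) < 2:
        raise ValueError("need >= 2 processing states to compare")
    rows = []
    raw_sample = block.get("raw", {}).get("sample")
    for state, fr in block.items():
        flagged = (
            raw_sample is not None
            and raw_sample > 0
            and fr["sample"] < 0.5 * raw_sample
        )
        rows.append(
            (state, fr["platform"], fr["sample"], bool(flagged))
        )
    out = pd.DataFrame(
        rows, columns=["state", "platform_fraction", "sample_fraction", "sample_loss_flag"]
    ).sort_values(["platform_fraction", "state"]).reset_index(drop=True)
    return out
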