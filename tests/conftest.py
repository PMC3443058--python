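"""Shared fixtures and helpers for the crossnorm test suite."""

import numpy as np
import pandas as pd
import pytest


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j:02d}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_batch_matrix(rng):
    """60 genes x (6+6) samples, batch 2 shifted by a known per-gene offset."""
    G = 60
    base = rng.normal(8.0, 2.0, size=(G, 1))
    shift = rng.normal(1.5, 0.5, size=(G, 1))
    b1 = base + rng.normal(0, 0.3, size=(G, 6))
    b2 = base + shift + rng.normal(0, 0.3, size=(G, 6))
    m = make_matrix(
        np.hstack([b1, b2]),
        samples=[f"A{j}" for j in range(6)] + [f"B{j}" for j in range(6)],
    )
    batches = pd.Series(
        ["P1"] * 6 + ["P2"] * 6, index=m.columns, name="platform"
    )
    return m, batches, shift.ravel()
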