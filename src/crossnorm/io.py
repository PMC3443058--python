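"""Readers and writers for the tab-delimited formats the pipeline exchanges.

The universal in-memory currency is a :class:`pandas.DataFrame` with gene
(or probe) IDs as the index and sample IDs as columns, holding log2-scale
intensities.  Detection-p-value matrices use the same layout.  Sample
design tables are DataFrames indexed by ``sample_id``.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mapping",
    "write_mapping",
    "read_design",
    "write_design",
    "validate_matrix",
]


def validate_matrix(matrix: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    """Check the expression-matrix invariants: unique IDs, finite values."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][:5].tolist()
        raise ValueError(f"{name}: duplicate row IDs, e.g. {dup}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][:5].tolist()
        raise ValueError(f"{name}: duplicate sample IDs, e.g. {dup}")
    if not matrix.map(lambda v: pd.notna(v)).all().all():
        raise ValueError(f"{name}: contains missing values")
    return matrix


def read_matrix(path) -> pd.DataFrame:
    """Read a gene/probe x sample TSV (first column = row ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_matrix(df, str(path))


def write_matrix(matrix: pd.DataFrame, path, id_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=id_label, float_format="%.10g")


def read_mapping(path) -> pd.DataFrame:
    """Read a two-column probe->gene mapping TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["probe_id", "gene_id"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df[expected]


def write_mapping(mapping: pd.DataFrame, path) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    """Read a sample design table indexed by sample_id; factors kept as strings."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")
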