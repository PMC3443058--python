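"""Consensus probe-to-gene re-annotation and gene-space alignment.

Probes are kept only when at least ``min_agree`` independent annotation
resources (e.g. reMOAT, BioMart, a BLAST-based search) agree on the same
Ensembl gene; probes with multi-resource support for two *different* genes
are discarded as ambiguous, so the consensus map is a function
probe -> gene.  Gene-level expression is the arithmetic mean of the mapped
probe rows on the log2 scale, and two platforms are aligned on the
intersection of their gene IDs in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMapResource",
    "ConsensusMap",
    "build_consensus_map",
    "collapse_to_genes",
    "align_gene_space",
]


@dataclass(frozen=True)
class ProbeMapResource:
    """One annotation resource: a set of (probe_id, gene_id) pairs.

    A probe may map to several genes within a single resource; duplicate
    pairs are collapsed.
    """

    name: str
    entries: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, name: str, pairs) -> "ProbeMapResource":
        entries = frozenset((str(p), str(g)) for p, g in pairs)
        for p, _ in entries:
            if not p:
                raise ValueError(f"resource {name!r}: empty probe_id")
        return cls(name=name, entries=entries)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "ProbeMapResource":
        return cls.from_pairs(name, frame[["probe_id", "gene_id"]].itertuples(index=False))


@dataclass
class ConsensusMap:
    """probe -> gene map surviving the >= min_agree agreement rule."""

    entries: dict  # probe_id -> gene_id
    provenance: dict  # probe_id -> number of supporting resources
    min_agree: int = 2

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries.items())
        return pd.DataFrame(
            {
                "probe_id": [p for p, _ in rows],
                "gene_id": [g for _, g in rows],
                "n_resources": [self.provenance[p] for p, _ in rows],
            }
        )


def build_consensus_map(resources, min_agree: int = 2) -> ConsensusMap:
    """Retain probe->gene pairs supported by >= ``min_agree`` resources.

    A probe reaching the support threshold for more than one gene is
    ambiguous and dropped entirely.  The result is independent of the
    order in which resources are supplied.
    """
    resources = list(resources)
    if min_agree < 2:
        raise ValueError("min_agree must be >= 2")
    if len(resources) < min_agree:
        raise ValueError(
            f"need at least {min_agree} resources, got {len(resources)}"
        )

    support: dict = {}
    for res in resources:
        for probe, gene in res.entries:
            support.setdefault(probe, {}).setdefault(gene, 0)
            support[probe][gene] += 1

    entries: dict = {}
    provenance: dict = {}
    for probe, genes in support.items():
        winners = [(g, c) for g, c in genes.items() if c >= min_agree]
        if len(winners) == 1:
            gene, count = winners[0]
            entries[probe] = gene
            provenance[probe] = count
        # zero winners: no agreement; >1 winner: ambiguous -> drop
    return ConsensusMap(entries=entries, provenance=provenance, min_agree=min_agree)


def collapse_to_genes(
    matrix: pd.DataFrame, consensus: ConsensusMap, method: str = "mean"
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Each gene row is the column-wise arithmetic mean of its mapped probe
    rows (log2 scale); unmapped probes are dropped and the output is sorted
    lexicographically by gene ID.
    """
    if method != "mean":
        raise ValueError(f"unsupported collapse method {method!r}")
    if not consensus.entries:
        raise ValueError("consensus map is empty")
    mapped = matrix.index.intersection(list(consensus.entries))
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix appears in the consensus map")
    sub = matrix.loc[mapped]
    genes = pd.Index([consensus.entries[p] for p in mapped], name="gene_id")
    collapsed = sub.groupby(genes).mean()
    return collapsed.sort_index()


def align_gene_space(a: pd.DataFrame, b: pd.DataFrame):
    """Restrict two gene-level matrices to their shared genes, same order."""
    common = a.index.intersection(b.index).sort_values()
    if len(common) == 0:
        raise ValueError("gene sets are disjoint: nothing to align")
    return a.loc[common].copy(), b.loc[common].copy()
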