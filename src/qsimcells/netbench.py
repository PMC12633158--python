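"""Correlation-network benchmarking against the programmed circuit topology.

Standard single-cell preprocessing (library-size normalization to a fixed
target, log1p, per-gene z-scoring) is followed by pooled-cell Pearson and
Spearman gene-gene correlation.  An adjacency is obtained by keeping edges
with ``|corr| > threshold`` (strict), and compared with the programmed
control-target list — the ground-truth regulatory topology — to report which
programmed links a correlation analysis recovers and which of its edges are
spurious.

Correlations are computed over all cells pooled (both cell types): the
cross-type dependencies written by inter-register gates are invisible within
a single type, where the partner gene is structurally zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .kernel import Topology
from .matrixgen import CountMatrix

__all__ = [
    "PreprocConfig",
    "PreprocessedMatrix",
    "NetworkResult",
    "TruthComparison",
    "preprocess",
    "correlation_network",
    "compare_to_truth",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing and thresholding knobs.

    target_sum: per-cell total after library-size normalization (counts).
    log1p / scale: toggles for the variance-stabilizing transform and the
    per-gene z-score.
    corr_threshold: absolute-correlation cutoff for edge retention.
    """

    target_sum: float = 10_000.0
    log1p: bool = True
    scale: bool = True
    corr_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must lie in (0, 1)")


@dataclass
class PreprocessedMatrix:
    """Genes x cells real matrix after normalize/log1p/scale.

    Zero-variance genes are excluded from ``values`` and listed in
    ``excluded_genes``; all-zero cells are left untouched and flagged.
    """

    values: np.ndarray
    gene_labels: List[str]
    cell_labels: List[str]
    cell_types: np.ndarray
    excluded_genes: List[str] = field(default_factory=list)
    zero_count_cells: List[str] = field(default_factory=list)


@dataclass
class NetworkResult:
    """Correlation matrix, thresholded adjacency and derived network."""

    method: str
    corr: pd.DataFrame
    adjacency: pd.DataFrame
    components: List[Set[str]]
    edge_list: pd.DataFrame
    threshold: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.corr.index)
        for row in self.edge_list.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, corr=float(row.corr))
        return g


def preprocess(matrix: CountMatrix, cfg: PreprocConfig = PreprocConfig()) -> PreprocessedMatrix:
    """Normalize per cell to ``target_sum``, log1p, z-score per gene.

    Runs through the scanpy preprocessing stack on an AnnData view and hands
    back a genes x cells array.  Cells whose total count is zero cannot be
    normalized; they are left as zeros and flagged.  Genes with zero variance
    after transformation carry no correlation signal and are excluded.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    import scanpy as sc

    adata = matrix.to_anndata()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    zero_cells = [matrix.cell_labels[j] for j in np.flatnonzero(totals == 0)]

    sc.pp.normalize_total(adata, target_sum=cfg.target_sum)
    if cfg.log1p:
        sc.pp.log1p(adata)

    dense = np.asarray(adata.X.todense(), dtype=np.float64)  # cells x genes
    variances = dense.var(axis=0)
    keep = variances > 0
    excluded = [g for g, k in zip(matrix.gene_labels, keep) if not k]
    dense = dense[:, keep]

    if cfg.scale:
        mean = dense.mean(axis=0)
        std = dense.std(axis=0)
        dense = (dense - mean) / std

    return PreprocessedMatrix(
        values=dense.T,
        gene_labels=[g for g, k in zip(matrix.gene_labels, keep) if k],
        cell_labels=list(matrix.cell_labels),
        cell_types=matrix.cell_types.copy(),
        excluded_genes=excluded,
        zero_count_cells=zero_cells,
    )


def correlation_network(
    pre: PreprocessedMatrix,
    method: str = "pearson",
    cfg: PreprocConfig = PreprocConfig(),
) -> NetworkResult:
    """Pairwise gene-gene correlation across pooled cells, thresholded.

    Spearman uses average ranks for ties (the scipy default), which matters
    here because structural and sampling zeros produce heavy ties.
    Adjacency keeps pairs with ``|corr| > cfg.corr_threshold`` strictly;
    ties with the threshold are excluded.
    """
    values = pre.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes after exclusion")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    if method == "pearson":
        corr = np.corrcoef(values)
    elif method == "spearman":
        corr, _ = scipy.stats.spearmanr(values, axis=1)
        if np.ndim(corr) == 0:  # scipy collapses the 2-variable case to a scalar
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    else:
        raise ValueError(f"unknown method {method!r}")

    labels = pre.gene_labels
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    adjacency = corr_df.abs() > cfg.corr_threshold
    np.fill_diagonal(adjacency.values, False)

    graph = nx.from_pandas_adjacency(adjacency.astype(int))
    components = [set(c) for c in nx.connected_components(graph)]

    rows = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency.iloc[i, j]:
                rows.append((labels[i], labels[j], float(corr_df.iloc[i, j])))
    edge_list = pd.DataFrame(rows, columns=["gene_a", "gene_b", "corr"])
    edge_list.insert(2, "method", method)

    return NetworkResult(
        method=method,
        corr=corr_df,
        adjacency=adjacency,
        components=components,
        edge_list=edge_list,
        threshold=cfg.corr_threshold,
    )


@dataclass
class TruthComparison:
    """Programmed-topology edges vs inferred network edges (undirected match)."""

    method: str
    recovered: List[Tuple[str, str]]
    missed: List[Tuple[str, str]]
    spurious: List[Tuple[str, str]]
    components: List[Set[str]]

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "recovered": [list(e) for e in self.recovered],
            "missed": [list(e) for e in self.missed],
            "spurious": [list(e) for e in self.spurious],
            "components": [sorted(c) for c in self.components],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = (
            [("truth_recovered", a, b) for a, b in self.recovered]
            + [("truth_missed", a, b) for a, b in self.missed]
            + [("spurious", a, b) for a, b in self.spurious]
        )
        pd.DataFrame(rows, columns=["status", "gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False
        )


def compare_to_truth(
    result: NetworkResult,
    truth: Topology,
    gene_labels: Sequence[str],
) -> TruthComparison:
    """Score an inferred network against the programmed control-target list.

    ``gene_labels[i]`` names the gene on qubit ``i``.  Matching is
    undirected: correlation networks carry no directionality.
    """
    if truth.max_index() >= len(gene_labels):
        raise ValueError("topology references a qubit with no gene label")
    known = set(result.corr.index)
    truth_edges = []
    for control, target in truth:
        a, b = gene_labels[control], gene_labels[target]
        if a not in known or b not in known:
            raise ValueError(f"truth edge ({a}, {b}) references unknown gene labels")
        truth_edges.append(tuple(sorted((a, b))))

    inferred = {
        tuple(sorted((r.gene_a, r.gene_b)))
        for r in result.edge_list.itertuples(index=False)
    }
    truth_set = set(truth_edges)
    recovered = [e for e in truth_edges if e in inferred]
    missed = [e for e in truth_edges if e not in inferred]
    spurious = sorted(inferred - truth_set)
    return TruthComparison(
        method=result.method,
        recovered=recovered,
        missed=missed,
        spurious=spurious,
        components=result.components,
    )
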