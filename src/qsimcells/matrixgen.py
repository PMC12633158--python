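"""From measurement histograms to scRNA-seq-like count matrices.

A measured bit string is one joint observation of all gene qubits.  Each
string with count ``C(b)`` contributes ``C(b)`` simulated cells.  In the
default *paired* split mode every shot yields two cells — one per cell type —
with the off-type model genes structurally zeroed (a CT1 cell never expresses
CT2 genes and vice versa).  The binary activation matrix is then augmented
into overdispersed counts: wherever a gene is ON, its entry is replaced by a
negative-binomial draw ``NB(r_i, p_i)`` with ``p_i = r_i / (mu_i + r_i)``
(mean ``mu_i``, variance ``mu_i + mu_i^2 / r_i``); OFF entries stay exactly
zero.  A block of always-ON housekeeping genes (high, stable expression)
provides the background library against which model genes are normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .kernel import GeneSpec

__all__ = [
    "NBParams",
    "BinaryMatrix",
    "CountMatrix",
    "histogram_to_binary",
    "nb_augment",
    "add_housekeeping_block",
    "write_outputs",
    "read_counts",
]

# defaults: model genes mu=5, r=1; housekeeping block 50 genes mu=80, r=6
DEFAULT_NB = (5.0, 1.0)
DEFAULT_HKG = (50, 80.0, 6.0)

#: dense CSV mirror is written only when the matrix has at most this many entries
CSV_MIRROR_MAX_ENTRIES = 2_000_000


@dataclass(frozen=True)
class NBParams:
    """Negative-binomial parameters for one gene: mean ``mu``, size ``r``."""

    mu: float
    r: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.r <= 0:
            raise ValueError(f"NB parameters must be positive, got mu={self.mu}, r={self.r}")

    @property
    def p_nb(self) -> float:
        """Success probability ``p = r / (mu + r)``; the NB mean is then ``mu``."""
        return self.r / (self.mu + self.r)

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.r

    @property
    def zero_probability(self) -> float:
        """P(NB draw == 0) = p**r — sampling zeros, distinct from structural ones."""
        return self.p_nb**self.r


@dataclass
class BinaryMatrix:
    """Genes x cells activation matrix X' with entries in {0, 1}."""

    values: np.ndarray
    gene_labels: List[str]
    cell_labels: List[str]
    cell_types: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape[0] != len(self.gene_labels):
            raise ValueError("gene label count does not match row count")
        if self.values.shape[1] != len(self.cell_labels) or self.values.shape[1] != len(self.cell_types):
            raise ValueError("cell label count does not match column count")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer count matrix with labels."""

    values: np.ndarray
    gene_labels: List[str]
    cell_labels: List[str]
    cell_types: np.ndarray
    gene_types: List[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.gene_types:
            self.gene_types = ["model"] * self.values.shape[0]
        if self.values.shape[0] != len(self.gene_labels):
            raise ValueError("gene label count does not match row count")
        if self.values.shape[1] != len(self.cell_labels):
            raise ValueError("cell label count does not match column count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, label: str) -> int:
        try:
            return self.gene_labels.index(label)
        except ValueError:
            raise KeyError(f"gene {label!r} not in matrix") from None

    def to_anndata(self):
        """Cells x genes AnnData view (the transposed scanpy convention)."""
        import anndata

        adata = anndata.AnnData(
            X=scipy.sparse.csr_matrix(self.values.T.astype(np.float64)),
            obs=pd.DataFrame(
                {"cell_type": pd.Categorical(self.cell_types)},
                index=self.cell_labels,
            ),
            var=pd.DataFrame({"gene_type": self.gene_types}, index=self.gene_labels),
        )
        return adata


def _expand_shots(hist) -> np.ndarray:
    """Histogram -> (n_shots x n_qubits) bit array, keys in sorted order."""
    n = hist.num_qubits
    rows = []
    for key in sorted(hist.counts):
        bits = np.frombuffer(key.encode(), dtype=np.uint8) - ord("0")
        rows.append(np.tile(bits.astype(np.int8), (hist.counts[key], 1)))
    return np.vstack(rows) if rows else np.zeros((0, n), dtype=np.int8)


def histogram_to_binary(
    hist,
    genes: Sequence[GeneSpec],
    split_mode: str = "paired",
) -> BinaryMatrix:
    """Expand a measurement histogram into the binary activation matrix X'.

    Parameters
    ----------
    hist:
        :class:`~qsimcells.sampling.MeasurementHistogram` with logical keys.
    genes:
        Gene specs whose global index matches the bit-string position.
    split_mode:
        ``"paired"`` (default): each shot becomes a CT1 cell (CT2 model genes
        structurally zeroed) plus a CT2 cell (CT1 genes zeroed); columns are
        all CT1 cells in shot order, then all CT2 cells.  Total cells =
        2 * n_shots.  ``"joint"``: one untyped cell per shot carrying every
        bit.
    """
    genes = sorted(genes, key=lambda g: g.global_index)
    if len(genes) != hist.num_qubits:
        raise ValueError(
            f"{len(genes)} genes but histogram strings have {hist.num_qubits} bits"
        )
    labels = [g.name for g in genes]
    bits = _expand_shots(hist)  # shots x genes
    ct1_mask = np.array([g.cell_type == "CT1" for g in genes])

    if split_mode == "paired":
        m = bits.shape[0]
        ct1_cells = bits * ct1_mask[None, :]
        ct2_cells = bits * (~ct1_mask)[None, :]
        values = np.vstack([ct1_cells, ct2_cells]).T
        cell_labels = [f"CT1_{j:05d}" for j in range(m)] + [
            f"CT2_{j:05d}" for j in range(m)
        ]
        cell_types = np.array(["CT1"] * m + ["CT2"] * m, dtype=object)
    elif split_mode == "joint":
        values = bits.T
        cell_labels = [f"cell_{j:05d}" for j in range(bits.shape[0])]
        cell_types = np.array(["joint"] * bits.shape[0], dtype=object)
    else:
        raise ValueError(f"unknown split_mode {split_mode!r}")

    return BinaryMatrix(
        values=values,
        gene_labels=labels,
        cell_labels=cell_labels,
        cell_types=cell_types,
    )


def nb_augment(
    binary: BinaryMatrix,
    params: Mapping[str, NBParams],
    seed: int | np.random.Generator,
) -> CountMatrix:
    """Replace ON entries with negative-binomial draws; OFF entries stay 0.

    Every gene label in ``binary`` must have an entry in ``params``.  Draws
    are independent across matrix entries and reproducible given the seed.
    """
    missing = [g for g in binary.gene_labels if g not in params]
    if missing:
        raise ValueError(f"missing NB parameters for genes: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = np.zeros(binary.values.shape, dtype=np.int64)
    for i, label in enumerate(binary.gene_labels):
        p = params[label]
        # draw a full row so the stream layout is independent of the mask
        draws = rng.negative_binomial(p.r, p.p_nb, size=binary.n_cells)
        counts[i] = np.where(binary.values[i] == 1, draws, 0)

    return CountMatrix(
        values=counts,
        gene_labels=list(binary.gene_labels),
        cell_labels=list(binary.cell_labels),
        cell_types=binary.cell_types.copy(),
        gene_types=["model"] * binary.n_genes,
    )


def add_housekeeping_block(
    matrix: CountMatrix,
    n_hkg: int = DEFAULT_HKG[0],
    mu_hkg: float = DEFAULT_HKG[1],
    r_hkg: float = DEFAULT_HKG[2],
    seed: int | np.random.Generator = 0,
) -> CountMatrix:
    """Append ``n_hkg`` always-ON housekeeping genes to every cell.

    Housekeeping rows carry independent ``NB(r_hkg, p)`` counts in both cell
    types — there is no binary mask, so they have no structural zeros (only
    the negligible NB sampling zeros, ``(r/(mu+r))**r``).
    """
    if n_hkg < 0:
        raise ValueError("n_hkg must be >= 0")
    if n_hkg == 0:
        return matrix
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = NBParams(mu=mu_hkg, r=r_hkg)
    block = rng.negative_binomial(p.r, p.p_nb, size=(n_hkg, matrix.n_cells))
    labels = [f"HKG_{i + 1:02d}" for i in range(n_hkg)]
    return CountMatrix(
        values=np.vstack([matrix.values, block]),
        gene_labels=list(matrix.gene_labels) + labels,
        cell_labels=list(matrix.cell_labels),
        cell_types=matrix.cell_types.copy(),
        gene_types=list(matrix.gene_types) + ["HKG"] * n_hkg,
        provenance=dict(matrix.provenance),
    )


def write_outputs(matrix: CountMatrix, out_dir) -> Dict[str, Path]:
    """Write MTX + genes.tsv + barcodes.tsv, a CSV mirror, and provenance JSON.

    The MatrixMarket file stores the genes x cells sparse integer matrix;
    ``genes.tsv`` and ``barcodes.tsv`` follow the CellRanger-style triple with
    an extra type column each.  Small matrices also get a dense
    ``counts.csv`` mirror.  All outputs are byte-deterministic for a given
    matrix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    sparse = scipy.sparse.csr_matrix(matrix.values).tocoo()
    paths["mtx"] = out / "matrix.mtx"
    scipy.io.mmwrite(paths["mtx"], sparse, field="integer")

    paths["genes"] = out / "genes.tsv"
    pd.DataFrame({"gene": matrix.gene_labels, "gene_type": matrix.gene_types}).to_csv(
        paths["genes"], sep="\t", index=False
    )
    paths["barcodes"] = out / "barcodes.tsv"
    pd.DataFrame(
        {"barcode": matrix.cell_labels, "cell_type": matrix.cell_types}
    ).to_csv(paths["barcodes"], sep="\t", index=False)

    if matrix.values.size <= CSV_MIRROR_MAX_ENTRIES:
        paths["csv"] = out / "counts.csv"
        pd.DataFrame(
            matrix.values, index=matrix.gene_labels, columns=matrix.cell_labels
        ).to_csv(paths["csv"])

    paths["provenance"] = out / "provenance.json"
    from . import __version__

    payload = {
        "package": "qsimcells",
        "version": __version__,
        "n_genes": matrix.n_genes,
        "n_cells": matrix.n_cells,
        **matrix.provenance,
    }
    with open(paths["provenance"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_counts(out_dir) -> CountMatrix:
    """Round-trip reader for :func:`write_outputs` (exact, integer-for-integer)."""
    out = Path(out_dir)
    values = np.asarray(scipy.io.mmread(out / "matrix.mtx").todense(), dtype=np.int64)
    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(out / "barcodes.tsv", sep="\t")
    provenance = {}
    prov_path = out / "provenance.json"
    if prov_path.exists():
        with open(prov_path) as fh:
            provenance = json.load(fh)
    return CountMatrix(
        values=values,
        gene_labels=genes["gene"].astype(str).tolist(),
        cell_labels=barcodes["barcode"].astype(str).tolist(),
        cell_types=barcodes["cell_type"].astype(str).to_numpy(dtype=object),
        gene_types=genes["gene_type"].astype(str).tolist(),
        provenance=provenance,
    )
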