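"""Ligand-receptor cell-cell communication scoring.

A deliberately minimal mass-action score: for a ligand-receptor pair with a
sender and a receiver cell type, let ``e_L`` be the mean library-normalized
(counts-per-10k, no log) ligand expression over sender cells and ``e_R`` the
receptor mean over receiver cells.  The communication score is the Hill
saturation

    S = (e_L * e_R) / (kh + e_L * e_R),            S in [0, 1)

with the saturation constant ``kh`` set data-adaptively to the median of the
``e_L * e_R`` products over the candidate pair database, so that the typical
candidate pair sits at the Hill midpoint ``S = 0.5`` and no candidate is
pushed into saturation.  Significance is assessed by a cell-type
label-permutation null, and conditions are compared by the fold change
``S_interacting / S_control`` — the contrast, not the absolute score, is the
designed readout for distinguishing mechanistic coupling from coincidental
co-expression.  When two conditions are contrasted, a single shared ``kh``
is computed from the candidate products of both, so the two scores live on
one scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrixgen import CountMatrix

__all__ = [
    "LRPair",
    "CCCResult",
    "normalized_gene_mean",
    "interaction_product",
    "default_saturation",
    "lr_score",
    "permutation_test",
    "score_pairs",
    "condition_contrast",
    "contrast_conditions",
    "read_lr_database",
    "write_lr_database",
]

EPS = 1e-9
DEFAULT_N_PERM = 99
DEFAULT_TARGET_SUM = 10_000.0


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair with sender/receiver cell types."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    annotation: str = "true_mechanistic"
    name: str = ""
    pathway: str = ""

    def __post_init__(self) -> None:
        if self.annotation not in ("true_mechanistic", "false_control"):
            raise ValueError(f"unknown annotation {self.annotation!r}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.ligand}_{self.receptor}")


@dataclass
class CCCResult:
    """Score and permutation p-value of one pair in one condition."""

    pair: LRPair
    score: float
    p_value: Optional[float] = None
    condition: str = ""
    kh: float = float("nan")


def _normalized(matrix: CountMatrix, target_sum: float) -> np.ndarray:
    values = matrix.values.astype(np.float64)
    lib = values.sum(axis=0)
    lib = np.where(lib == 0, 1.0, lib)
    return values * (target_sum / lib)


def normalized_gene_mean(
    matrix: CountMatrix,
    gene: str,
    cell_type: str,
    target_sum: float = DEFAULT_TARGET_SUM,
    cell_types: Optional[np.ndarray] = None,
) -> float:
    """Mean counts-per-``target_sum`` of ``gene`` over cells of ``cell_type``."""
    types = matrix.cell_types if cell_types is None else cell_types
    mask = types == cell_type
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    row = _normalized(matrix, target_sum)[matrix.gene_index(gene)]
    return float(row[mask].mean())


def interaction_product(
    matrix: CountMatrix,
    pair: LRPair,
    target_sum: float = DEFAULT_TARGET_SUM,
    cell_types: Optional[np.ndarray] = None,
) -> float:
    """``e_L * e_R`` for one pair (ligand over senders, receptor over receivers)."""
    e_l = normalized_gene_mean(matrix, pair.ligand, pair.sender, target_sum, cell_types)
    e_r = normalized_gene_mean(matrix, pair.receptor, pair.receiver, target_sum, cell_types)
    return e_l * e_r


def default_saturation(products: Sequence[float]) -> float:
    """Median candidate product, floored at machine epsilon.

    Placing ``kh`` at the median puts the typical candidate pair at the Hill
    midpoint, keeping the score responsive over the whole observed range of
    products (a smaller constant saturates the strong pairs and compresses
    their fold changes).
    """
    if len(products) == 0:
        raise ValueError("need at least one candidate product")
    return max(float(np.median(products)), np.finfo(float).eps)


def lr_score(
    matrix: CountMatrix,
    pair: LRPair,
    kh: Optional[float] = None,
    candidate_pairs: Optional[Sequence[LRPair]] = None,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> float:
    """Hill-saturated mass-action communication score ``S in [0, 1)``.

    If ``kh`` is not given it is derived from ``candidate_pairs`` (defaulting
    to just ``pair``) via :func:`default_saturation` on this matrix.
    """
    product = interaction_product(matrix, pair, target_sum)
    if kh is None:
        candidates = candidate_pairs if candidate_pairs is not None else [pair]
        kh = default_saturation(
            [interaction_product(matrix, p, target_sum) for p in candidates]
        )
    if kh <= 0:
        raise ValueError("kh must be positive")
    return product / (kh + product)


def permutation_test(
    matrix: CountMatrix,
    pair: LRPair,
    kh: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> float:
    """Cell-type label-shuffle p-value for one pair.

    ``p = (1 + #{S_perm >= S_obs}) / (1 + n_perm)``; the smallest attainable
    p-value is ``1 / (1 + n_perm)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = interaction_product(matrix, pair, target_sum)
    s_obs = observed / (kh + observed)
    exceed = 0
    labels = matrix.cell_types.copy()
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        prod = interaction_product(matrix, pair, target_sum, cell_types=perm)
        if prod / (kh + prod) >= s_obs - 1e-15:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def score_pairs(
    matrix: CountMatrix,
    pairs: Sequence[LRPair],
    kh: Optional[float] = None,
    n_perm: Optional[int] = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    condition: str = "",
    target_sum: float = DEFAULT_TARGET_SUM,
) -> List[CCCResult]:
    """Score every pair of a database on one matrix, with optional p-values."""
    if not pairs:
        raise ValueError("empty pair database")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    products = [interaction_product(matrix, p, target_sum) for p in pairs]
    if kh is None:
        kh = default_saturation(products)
    results = []
    for pair, product in zip(pairs, products):
        score = product / (kh + product)
        p_value = (
            permutation_test(matrix, pair, kh, n_perm, rng, target_sum)
            if n_perm
            else None
        )
        results.append(
            CCCResult(pair=pair, score=score, p_value=p_value, condition=condition, kh=kh)
        )
    return results


def condition_contrast(
    results_control: Sequence[CCCResult],
    results_interacting: Sequence[CCCResult],
    eps: float = EPS,
) -> pd.DataFrame:
    """Per-pair fold change ``S_interacting / max(S_control, eps)``.

    Both result lists must cover the same pairs in the same order.  A control
    score of (numerically) zero yields an ``unbounded`` flag — the fold
    change is then only a lower bound against ``eps``.
    """
    if [r.pair for r in results_control] != [r.pair for r in results_interacting]:
        raise ValueError("control and interacting results cover different pairs")
    rows = []
    for ctrl, inter in zip(results_control, results_interacting):
        unbounded = ctrl.score <= eps
        fc = inter.score / max(ctrl.score, eps)
        rows.append(
            {
                "interaction_name": ctrl.pair.name,
                "source": ctrl.pair.sender,
                "target": ctrl.pair.receiver,
                "ligand": ctrl.pair.ligand,
                "receptor": ctrl.pair.receptor,
                "annotation": ctrl.pair.annotation,
                "score_control": ctrl.score,
                "score_interacting": inter.score,
                "pval_control": ctrl.p_value,
                "pval_interacting": inter.p_value,
                "fold_change": fc,
                "unbounded": unbounded,
            }
        )
    return pd.DataFrame(rows)


def contrast_conditions(
    matrix_control: CountMatrix,
    matrix_interacting: CountMatrix,
    pairs: Sequence[LRPair],
    n_perm: Optional[int] = DEFAULT_N_PERM,
    seed: int = 0,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> pd.DataFrame:
    """Score both conditions under one shared ``kh`` and tabulate fold changes.

    The shared saturation constant is the median of candidate products pooled
    across the two conditions, so the two score columns are directly
    comparable.
    """
    prods = [interaction_product(matrix_control, p, target_sum) for p in pairs] + [
        interaction_product(matrix_interacting, p, target_sum) for p in pairs
    ]
    kh = default_saturation(prods)
    ss = np.random.SeedSequence(seed).spawn(2)
    ctrl = score_pairs(
        matrix_control, pairs, kh=kh, n_perm=n_perm,
        seed=np.random.default_rng(ss[0]), condition="control", target_sum=target_sum,
    )
    inter = score_pairs(
        matrix_interacting, pairs, kh=kh, n_perm=n_perm,
        seed=np.random.default_rng(ss[1]), condition="interacting", target_sum=target_sum,
    )
    return condition_contrast(ctrl, inter)


_DB_COLUMNS = ["interaction_name", "pathway", "ligand", "receptor", "annotation", "evidence"]


def write_lr_database(pairs: Sequence[LRPair], path) -> None:
    """TSV database: interaction_name, pathway, ligand, receptor, annotation, evidence."""
    rows = [
        {
            "interaction_name": p.name,
            "pathway": p.pathway,
            "ligand": p.ligand,
            "receptor": p.receptor,
            "annotation": p.annotation,
            "evidence": p.pathway or p.name,
            "sender": p.sender,
            "receiver": p.receiver,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lr_database(path) -> List[LRPair]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("ligand", "receptor", "sender", "receiver") if c not in df]
    if missing:
        raise ValueError(f"LR database missing columns: {missing}")
    return [
        LRPair(
            ligand=str(r.ligand),
            receptor=str(r.receptor),
            sender=str(r.sender),
            receiver=str(r.receiver),
            annotation=str(getattr(r, "annotation", "true_mechanistic")),
            name=str(getattr(r, "interaction_name", "")),
            pathway=str(getattr(r, "pathway", "")),
        )
        for r in df.itertuples(index=False)
    ]
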