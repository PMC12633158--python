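"""End-to-end orchestration: circuit -> histogram -> counts -> benchmarks."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import networkx as nx
import numpy as np

from . import __version__
from .cccbench import contrast_conditions, score_pairs, write_lr_database
from .config import ExperimentConfig, save_config
from .kernel import build_final_state, exact_distribution
from .matrixgen import (
    CountMatrix,
    add_housekeeping_block,
    histogram_to_binary,
    nb_augment,
    write_outputs,
)
from .netbench import (
    NetworkResult,
    TruthComparison,
    compare_to_truth,
    correlation_network,
    preprocess,
)
from .sampling import MeasurementHistogram, sample_shots

__all__ = ["RunResult", "simulate_counts", "run_case", "contrast_cases"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: ExperimentConfig
    histogram: MeasurementHistogram
    counts: CountMatrix
    networks: Dict[str, NetworkResult] = field(default_factory=dict)
    truth_reports: Dict[str, TruthComparison] = field(default_factory=dict)
    ccc_results: Optional[list] = None
    out_dir: Optional[Path] = None


def _stage(name):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"[{name}] {exc}") from exc
            return False

    return _ctx()


def _child_rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_counts(config: ExperimentConfig) -> tuple:
    """Quantum sampling + count-matrix generation for one configuration."""
    rng_shots, rng_nb, rng_hkg = _child_rngs(config.seed, 3)
    genes = config.gene_specs()

    with _stage("qkernel"):
        state = build_final_state(genes, config.topology_sequence())
        dist = exact_distribution(state)
        hist = sample_shots(dist, config.shots, rng_shots)
        hist.config = {"name": config.name, "seed": config.seed, "shots": config.shots}

    with _stage("matrixgen"):
        binary = histogram_to_binary(hist, genes, split_mode=config.split_mode)
        counts = nb_augment(binary, config.nb_params(), rng_nb)
        counts = add_housekeeping_block(
            counts, n_hkg=config.hkg.n, mu_hkg=config.hkg.mu, r_hkg=config.hkg.r,
            seed=rng_hkg,
        )
        counts.provenance = {
            "config": config.model_dump(mode="json"),
            "seed": config.seed,
        }
    return hist, counts


def run_case(config: ExperimentConfig, out_dir=None) -> RunResult:
    """Execute the full pipeline and (optionally) write the artifact set.

    Stages: quantum kernel -> matrix generation -> correlation-network
    benchmark (Pearson and Spearman, with truth comparison) -> LR scoring on
    this condition alone.  With ``out_dir`` set, writes config, histogram,
    the count-matrix triple, edge lists, GraphML networks, truth reports,
    CCC scores and a run log.
    """
    t0 = time.time()
    hist, counts = simulate_counts(config)
    result = RunResult(config=config, histogram=hist, counts=counts)

    with _stage("netbench"):
        pre = preprocess(counts, config.preproc_config())
        truth = config.truth_topology()
        gene_labels = [g.name for g in config.gene_specs()]
        for method in ("pearson", "spearman"):
            net = correlation_network(pre, method, config.preproc_config())
            result.networks[method] = net
            if len(truth):
                result.truth_reports[method] = compare_to_truth(net, truth, gene_labels)

    pairs = config.lr_pair_objects()
    if pairs:
        with _stage("cccbench"):
            (rng_perm,) = _child_rngs(config.seed + 1_000_003, 1)
            result.ccc_results = score_pairs(
                counts, pairs, n_perm=99, seed=rng_perm, condition=config.name
            )

    if out_dir is not None:
        with _stage("write"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_config(config, out / "config.json")
            hist.to_json(out / "histogram.json")
            write_outputs(counts, out)
            for method, net in result.networks.items():
                net.edge_list.to_csv(out / f"edges_{method}.tsv", sep="\t", index=False)
                nx.write_graphml(net.graph(), out / f"network_{method}.graphml")
            for method, report in result.truth_reports.items():
                report.to_json(out / f"truth_{method}.json")
                report.to_tsv(out / f"truth_{method}.tsv")
            if pairs:
                write_lr_database(pairs, out / "lr_database.tsv")
            if result.ccc_results is not None:
                import pandas as pd

                pd.DataFrame(
                    [
                        {
                            "source": r.pair.sender,
                            "target": r.pair.receiver,
                            "ligand": r.pair.ligand,
                            "receptor": r.pair.receptor,
                            "prob": r.score,
                            "pval": r.p_value,
                            "pathway": r.pair.pathway,
                            "dataset": config.name,
                        }
                        for r in result.ccc_results
                    ]
                ).to_csv(out / "ccc_scores.tsv", sep="\t", index=False)
            (out / "run.log").write_text(
                f"qsimcells {__version__}\n"
                f"case: {config.name}\nseed: {config.seed}\n"
                f"shots: {config.shots}\ncells: {counts.n_cells}\n"
                f"genes: {counts.n_genes}\n"
                f"elapsed_s: {time.time() - t0:.2f}\n"
            )
            result.out_dir = out
    return result


def contrast_cases(
    config_control: ExperimentConfig,
    config_interacting: ExperimentConfig,
    n_perm: Optional[int] = 99,
    out_path=None,
):
    """Simulate both conditions and tabulate LR fold changes (shared kh)."""
    pairs = config_interacting.lr_pair_objects() or config_control.lr_pair_objects()
    if not pairs:
        raise ValueError("no LR pairs configured")
    _, counts_control = simulate_counts(config_control)
    _, counts_interacting = simulate_counts(config_interacting)
    table = contrast_conditions(
        counts_control,
        counts_interacting,
        pairs,
        n_perm=n_perm,
        seed=config_control.seed + 2_000_003,
    )
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
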