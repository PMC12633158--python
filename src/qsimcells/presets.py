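"""Bundled experiment presets and tiny hand-checkable fixtures.

The two shipped experiments use a 10-gene system: five genes per cell type,
with per-gene activation proportions chosen to span the full range from
nearly-always-OFF to nearly-always-ON:

* **case1** — an inter-register cascade ``(3,5), (5,7), (7,0)``: a CT1 gene
  activates a CT2 gene, which activates a second CT2 gene, which feeds back
  onto a CT1 gene.  This is the "communication on" condition.
* **case2** — a non-communicating control with a single intra-CT1 link
  ``(2,1)`` and no cross-register gates.

Both share the same activation angles, negative-binomial parameters
(model genes mu=5, r=1), a 50-gene housekeeping block (mu=80, r=6) and the
same ligand-receptor candidate database: two mechanistic pairs that ride the
cascade (g3->g5, g7->g0) and two false controls picked among highly expressed
but uncoupled genes (g8->g4, g9->g4).
"""

from __future__ import annotations

from typing import Dict, Optional

from .config import (
    ExperimentConfig,
    GeneConfig,
    LRPairConfig,
    TopologiesConfig,
)

__all__ = [
    "DEMO_ACTIVATIONS",
    "CASCADE_PAIRS",
    "CONTROL_PAIRS",
    "case1_config",
    "case2_config",
    "make_fixtures",
    "FIXTURE_KINDS",
]

#: Activation proportions p_i = theta_i / pi for genes g0..g9 (g0-g4: CT1).
DEMO_ACTIVATIONS = (0.2, 0.1, 0.4, 0.9, 0.8, 0.2, 0.3, 0.2, 0.7, 0.5)

#: Inter-register cascade topology (global qubit indices, time-ordered).
CASCADE_PAIRS = ((3, 5), (5, 7), (7, 0))

#: Non-communicating control: one intra-CT1 link.
CONTROL_PAIRS = ((2, 1),)

DEFAULT_SHOTS = 2000

FIXTURE_KINDS = ("tiny-2gene", "case1", "case2", "null-independent")


def _demo_genes() -> list:
    return [
        GeneConfig(
            name=f"g{i}",
            activation=a,
            cell_type="CT1" if i < 5 else "CT2",
        )
        for i, a in enumerate(DEMO_ACTIVATIONS)
    ]


def _demo_lr_pairs() -> list:
    return [
        LRPairConfig(
            ligand="g3", receptor="g5", sender="CT1", receiver="CT2",
            annotation="true_mechanistic", name="g3_g5_simulated", pathway="Simulated1",
        ),
        LRPairConfig(
            ligand="g7", receptor="g0", sender="CT2", receiver="CT1",
            annotation="true_mechanistic", name="g7_g0_simulated", pathway="Simulated2",
        ),
        LRPairConfig(
            ligand="g8", receptor="g4", sender="CT2", receiver="CT1",
            annotation="false_control", name="g8_g4_simulated", pathway="Simulated3",
        ),
        LRPairConfig(
            ligand="g9", receptor="g4", sender="CT2", receiver="CT1",
            annotation="false_control", name="g9_g4_simulated", pathway="Simulated4",
        ),
    ]


def case1_config(seed: int = 0, shots: int = DEFAULT_SHOTS) -> ExperimentConfig:
    """Inter-register cascade ("interacting") experiment."""
    return ExperimentConfig(
        name="case1",
        genes=_demo_genes(),
        topologies=TopologiesConfig(inter=list(CASCADE_PAIRS)),
        shots=shots,
        seed=seed,
        lr_pairs=_demo_lr_pairs(),
    )


def case2_config(seed: int = 0, shots: int = DEFAULT_SHOTS) -> ExperimentConfig:
    """Non-communicating control experiment."""
    return ExperimentConfig(
        name="case2",
        genes=_demo_genes(),
        topologies=TopologiesConfig(intra_ct1=list(CONTROL_PAIRS)),
        shots=shots,
        seed=seed,
        lr_pairs=_demo_lr_pairs(),
    )


def make_fixtures(kind: str, seed: int = 0) -> Dict[str, object]:
    """Small, hand-checkable inputs for tests and demos.

    Returns a dict with at least ``config``; tiny deterministic kinds also
    carry ``expected_distribution`` (logical bit string -> probability).
    """
    if kind == "tiny-2gene":
        config = ExperimentConfig(
            name="tiny-2gene",
            genes=[
                GeneConfig(name="gA", activation=1.0, cell_type="CT1"),
                GeneConfig(name="gB", activation=0.0, cell_type="CT2"),
            ],
            topologies=TopologiesConfig(inter=[(0, 1)]),
            shots=100,
            seed=seed,
            hkg={"n": 0},
        )
        # gA is deterministically ON and flips gB: all mass on "11"
        return {"config": config, "expected_distribution": {"11": 1.0}}
    if kind == "null-independent":
        config = ExperimentConfig(
            name="null-independent",
            genes=_demo_genes(),
            topologies=TopologiesConfig(),
            shots=DEFAULT_SHOTS,
            seed=seed,
        )
        return {"config": config}
    if kind == "case1":
        return {"config": case1_config(seed=seed)}
    if kind == "case2":
        return {"config": case2_config(seed=seed)}
    raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
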