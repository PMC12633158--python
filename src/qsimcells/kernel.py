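"""Statevector engine for the quantum generative kernel.

Each gene is represented by one qubit.  A parameterized circuit is built in
three stages:

1. *Initialization* — every qubit starts in ``|0>`` ("OFF") and receives a
   Y-axis rotation ``Ry(theta_i)``, where ``theta_i = activation_i * pi``.
   The activation proportion maps 0 to a gene that is always OFF and 1 to a
   gene that is always ON; intermediate values put the qubit in a
   superposition with measurement probability ``P(ON) = sin^2(theta_i / 2)``.
2. *Regulation* — an ordered list of CNOT (CX) gates couples control genes to
   target genes.  CX flips the target basis bit wherever the control bit is
   1, so a sequence of CX gates encodes a directed, time-ordered regulatory
   cascade.  The gates do not commute: order is semantic.
3. *Cell-cell communication* — two cell-type registers are combined by a
   tensor product, and further CX gates spanning both registers encode
   ligand-receptor coupling between cell types.

All gates used here (Ry on ``|0>`` products, CX) have real matrices, so the
state is stored as a dense real amplitude vector.  Amplitude index ``k``
encodes qubit ``i`` in bit ``(k >> i) & 1`` — i.e. gene ``i`` always lives at
string position ``i`` of the *logical* bit string ``b0 b1 ... b_{n-1}``.
Raw little-endian simulator strings (highest qubit printed first) are the
reverse of logical strings; the re-keying to logical order happens exactly
once, in :func:`exact_distribution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Sequence, Tuple

import numpy as np

__all__ = [
    "MAX_QUBITS",
    "GeneSpec",
    "Topology",
    "CircuitState",
    "prepare_initial_state",
    "apply_cx_sequence",
    "combine_registers",
    "build_final_state",
    "exact_distribution",
    "index_to_bitstring",
    "bitstring_to_index",
    "reverse_bitstring",
]

#: Hard cap on register width: the engine stores all 2**n amplitudes densely.
MAX_QUBITS = 20

_NORM_TOL = 1e-12


class ConfigurationError(ValueError):
    """Raised for inconsistent gene registers or gate topologies."""


@dataclass(frozen=True)
class GeneSpec:
    """One gene qubit: activation angle, register membership, indexing.

    Parameters
    ----------
    name:
        Gene label (e.g. ``"g3"``).
    activation:
        Proportional initial activation ``p_i = theta_i / pi`` in ``[0, 1]``.
        Note this is *not* the Bernoulli ON-probability; that is
        ``sin^2(theta_i / 2)`` and is exposed as :attr:`p_on`.
    cell_type:
        ``"CT1"`` or ``"CT2"``.
    global_index:
        Qubit index in the combined register (CT1 first, then CT2).
    local_index:
        Index within the gene's own cell-type register.
    """

    name: str
    activation: float
    cell_type: str
    global_index: int
    local_index: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise ConfigurationError(
                f"gene {self.name!r}: activation {self.activation} outside [0, 1]"
            )
        if self.cell_type not in ("CT1", "CT2"):
            raise ConfigurationError(
                f"gene {self.name!r}: cell_type must be 'CT1' or 'CT2'"
            )

    @property
    def theta(self) -> float:
        """Rotation angle in radians, ``theta = activation * pi``."""
        return self.activation * math.pi

    @property
    def p_on(self) -> float:
        """Marginal probability of measuring this qubit ON, ``sin^2(theta/2)``."""
        return math.sin(self.theta / 2.0) ** 2


@dataclass(frozen=True)
class Topology:
    """Ordered list of (control, target) qubit pairs for a CX sequence.

    The order of ``pairs`` is preserved and semantically meaningful: CX gates
    on overlapping qubits do not commute, and cascades rely on earlier gates
    feeding later ones.  ``scope`` documents whether the pairs couple genes
    within one register (``"intra"``), across registers (``"inter"``) or a
    mixture; it does not change the applied unitary.
    """

    pairs: Tuple[Tuple[int, int], ...]
    scope: str = "mixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((int(c), int(t)) for c, t in self.pairs))
        for control, target in self.pairs:
            if control == target:
                raise ConfigurationError(
                    f"CX pair ({control}, {target}): control and target coincide"
                )
            if control < 0 or target < 0:
                raise ConfigurationError(
                    f"CX pair ({control}, {target}): negative qubit index"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        return iter(self.pairs)

    def max_index(self) -> int:
        return max((max(c, t) for c, t in self.pairs), default=-1)


@dataclass
class CircuitState:
    """Dense real statevector over ``num_qubits`` gene qubits."""

    num_qubits: int
    amplitudes: np.ndarray
    stage: str = "psi0"

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.shape != (2**self.num_qubits,):
            raise ConfigurationError(
                f"amplitude vector has shape {self.amplitudes.shape}, "
                f"expected ({2**self.num_qubits},)"
            )
        norm = float(np.sum(self.amplitudes**2))
        if abs(norm - 1.0) > 1e-9:
            raise ConfigurationError(f"state is not normalized: sum amp^2 = {norm}")

    def probabilities(self) -> np.ndarray:
        """Squared amplitudes, indexed by the little-endian integer ``k``."""
        return self.amplitudes**2

    def marginal_on(self, qubit: int) -> float:
        """Exact probability that ``qubit`` measures 1."""
        idx = np.arange(2**self.num_qubits)
        mask = ((idx >> qubit) & 1).astype(bool)
        return float(np.sum(self.amplitudes[mask] ** 2))


def _check_qubit_count(n: int) -> None:
    if n < 1:
        raise ConfigurationError("need at least one qubit")
    if n > MAX_QUBITS:
        raise ConfigurationError(
            f"{n} qubits exceeds the dense statevector cap of {MAX_QUBITS}"
        )


def _validate_contiguous(genes: Sequence[GeneSpec]) -> None:
    indices = [g.global_index for g in genes]
    if sorted(indices) != indices:
        raise ConfigurationError("genes must be sorted by global_index")
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise ConfigurationError(
            f"global indices {indices} are not contiguous / contain duplicates"
        )


def prepare_initial_state(genes: Sequence[GeneSpec]) -> CircuitState:
    """Build the product state ``psi0`` of independently rotated qubits.

    Each gene contributes the single-qubit state
    ``cos(theta/2)|0> + sin(theta/2)|1>``.  Genes must be sorted by
    ``global_index`` and contiguous; the first gene is mapped to qubit 0 of
    the returned register (registers that start at a nonzero global index are
    built in local order and shifted by :func:`combine_registers`).
    """
    if not genes:
        raise ConfigurationError("empty gene list")
    _validate_contiguous(genes)
    _check_qubit_count(len(genes))
    amps = np.array([1.0])
    for gene in genes:
        half = gene.theta / 2.0
        single = np.array([math.cos(half), math.sin(half)])
        # kron(new, old) keeps earlier qubits in the low-order bits
        amps = np.kron(single, amps)
    return CircuitState(num_qubits=len(genes), amplitudes=amps, stage="psi0")


def apply_cx_sequence(
    state: CircuitState, topology: Topology, stage: str | None = None
) -> CircuitState:
    """Apply a time-ordered CX sequence; first listed pair acts first.

    Each CX is a permutation of the computational basis:
    ``b_target <- b_target XOR b_control``.  The amplitude multiset (hence
    the norm) is preserved.
    """
    if topology.max_index() >= state.num_qubits:
        raise ConfigurationError(
            f"topology references qubit {topology.max_index()} "
            f"but the register has only {state.num_qubits} qubits"
        )
    amps = state.amplitudes
    idx = np.arange(2**state.num_qubits)
    for control, target in topology:
        perm = idx ^ (((idx >> control) & 1) << target)
        amps = amps[perm]
    return CircuitState(
        num_qubits=state.num_qubits,
        amplitudes=amps,
        stage=stage if stage is not None else state.stage,
    )


def combine_registers(
    ct1_genes: Sequence[GeneSpec], ct2_genes: Sequence[GeneSpec]
) -> CircuitState:
    """Tensor two independent cell-type registers into one state (``psi2``).

    CT1 genes must occupy global indices ``0..n-1`` and CT2 genes
    ``n..n+n'-1``.  Before any cross-register gates the two registers are
    statistically independent: every cross-register covariance is zero.
    """
    n, n2 = len(ct1_genes), len(ct2_genes)
    if not n or not n2:
        raise ConfigurationError("both registers must be non-empty")
    if [g.global_index for g in ct1_genes] != list(range(n)):
        raise ConfigurationError("CT1 global indices must be 0..n-1")
    if [g.global_index for g in ct2_genes] != list(range(n, n + n2)):
        raise ConfigurationError("CT2 global indices must be n..n+n'-1")
    _check_qubit_count(n + n2)

    local_ct1 = [
        GeneSpec(g.name, g.activation, g.cell_type, i, g.local_index)
        for i, g in enumerate(ct1_genes)
    ]
    local_ct2 = [
        GeneSpec(g.name, g.activation, g.cell_type, i, g.local_index)
        for i, g in enumerate(ct2_genes)
    ]
    psi_ct1 = prepare_initial_state(local_ct1)
    psi_ct2 = prepare_initial_state(local_ct2)
    # CT1 occupies the low-order bits of the combined index
    amps = np.kron(psi_ct2.amplitudes, psi_ct1.amplitudes)
    return CircuitState(num_qubits=n + n2, amplitudes=amps, stage="psi2")


def build_final_state(
    genes: Sequence[GeneSpec],
    topologies: Iterable[Topology],
) -> CircuitState:
    """Full circuit: rotated product state, then every topology in order.

    ``topologies`` are applied sequentially in the order given (intra-register
    lists first, then the inter-register communication list, by convention).
    Gates acting on disjoint qubit sets commute with the tensor product, so
    applying intra-register gates after combining registers yields the same
    final state as applying them on the separate registers.
    """
    genes = sorted(genes, key=lambda g: g.global_index)
    _validate_contiguous(genes)
    if genes[0].global_index != 0:
        raise ConfigurationError("global indices must start at 0")
    ct1 = [g for g in genes if g.cell_type == "CT1"]
    ct2 = [g for g in genes if g.cell_type == "CT2"]
    if ct1 and ct2:
        state = combine_registers(ct1, ct2)
    else:
        state = prepare_initial_state(genes)
    for topology in topologies:
        state = apply_cx_sequence(state, topology)
    state.stage = "psifinal"
    return state


def index_to_bitstring(index: int, num_qubits: int) -> str:
    """Logical bit string ``b0 b1 ... b_{n-1}`` for amplitude index ``index``."""
    return "".join(str((index >> i) & 1) for i in range(num_qubits))


def bitstring_to_index(bits: str) -> int:
    """Inverse of :func:`index_to_bitstring`."""
    return sum((1 << i) for i, b in enumerate(bits) if b == "1")


def reverse_bitstring(bits: str) -> str:
    """Swap between logical order and the raw little-endian printing order."""
    return bits[::-1]


def exact_distribution(state: CircuitState) -> Dict[str, float]:
    """Exact outcome distribution keyed by *logical* bit strings.

    Probabilities are the squared amplitudes.  The little-endian integer
    index is rendered so that string position ``i`` holds gene ``i`` — this
    is the single place where the raw simulator printing order is reversed
    into logical gene order.  Outcomes that are zero up to floating-point
    residue (p < 1e-14, e.g. cos(pi/2)^2) are omitted.
    """
    probs = state.probabilities()
    n = state.num_qubits
    return {
        index_to_bitstring(k, n): float(p)
        for k, p in enumerate(probs)
        if p > 1e-14
    }
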