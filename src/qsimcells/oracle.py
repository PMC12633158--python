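"""Classical push-forward oracle for the Ry/CX gene circuit.

The circuit's initial state is a product of non-negative single-qubit
superpositions, so measuring it is equivalent to drawing each gene bit
independently as Bernoulli(sin^2(theta_i/2)).  Every CX gate is a permutation
of basis states, acting on a sampled bit pattern as the XOR update
``b_target <- b_target XOR b_control``.  The exact outcome distribution is
therefore the push-forward of the independent-Bernoulli product measure
through the composed XOR map, computed here by enumeration over all
``2**n`` patterns.

This module is deliberately independent of :mod:`qsimcells.kernel` (no
amplitudes, no gates) and serves as its cross-validation oracle.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence

import numpy as np

from .kernel import ConfigurationError, GeneSpec, Topology, index_to_bitstring

__all__ = ["pushforward_distribution", "MAX_ORACLE_QUBITS"]

#: Enumeration guard: 2**20 patterns is the most this oracle will tabulate.
MAX_ORACLE_QUBITS = 20


def pushforward_distribution(
    genes: Sequence[GeneSpec],
    topologies: Iterable[Topology],
) -> Dict[str, float]:
    """Exact outcome distribution by classical enumeration.

    Parameters
    ----------
    genes:
        Gene specs sorted by global index, contiguous from 0.
    topologies:
        Topologies in circuit application order; their pairs are applied as
        sequential XOR updates.

    Returns
    -------
    dict
        Logical bit string -> probability, zero-probability outcomes omitted.
    """
    genes = sorted(genes, key=lambda g: g.global_index)
    n = len(genes)
    if n == 0:
        raise ConfigurationError("empty gene list")
    if n > MAX_ORACLE_QUBITS:
        raise ConfigurationError(
            f"{n} qubits exceeds the oracle enumeration guard of {MAX_ORACLE_QUBITS}"
        )
    if [g.global_index for g in genes] != list(range(n)):
        raise ConfigurationError("global indices must be contiguous from 0")

    idx = np.arange(2**n)
    probs = np.ones(2**n)
    for gene in genes:
        bit = (idx >> gene.global_index) & 1
        p = gene.p_on
        probs *= np.where(bit == 1, p, 1.0 - p)

    out = idx.copy()
    for topology in topologies:
        if topology.max_index() >= n:
            raise ConfigurationError(
                f"topology references qubit {topology.max_index()} of a "
                f"{n}-qubit system"
            )
        for control, target in topology:
            out = out ^ (((out >> control) & 1) << target)

    dist = np.zeros(2**n)
    np.add.at(dist, out, probs)
    return {
        index_to_bitstring(k, n): float(p) for k, p in enumerate(dist) if p > 0.0
    }
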