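"""Shot sampling: turn an exact outcome distribution into a measurement histogram.

The number of shots plays the role of the number of simulated single-cell
observations.  Sampling is a single multinomial draw over the exact
distribution — statistically identical to per-shot measurement and much
faster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

__all__ = ["MeasurementHistogram", "sample_shots"]


@dataclass
class MeasurementHistogram:
    """Counts ``C(b)`` per logical bit string, summing to ``n_shots``."""

    counts: Dict[str, int]
    n_shots: int
    config: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n_shots:
            raise ValueError(
                f"histogram counts sum to {total}, expected n_shots={self.n_shots}"
            )
        lengths = {len(b) for b in self.counts}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent bit-string lengths: {sorted(lengths)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count in histogram")

    @property
    def num_qubits(self) -> int:
        return len(next(iter(self.counts)))

    def to_json(self, path) -> None:
        payload = {
            "n_shots": self.n_shots,
            "counts": dict(sorted(self.counts.items())),
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MeasurementHistogram":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            counts={k: int(v) for k, v in payload["counts"].items()},
            n_shots=int(payload["n_shots"]),
            config=payload.get("config"),
        )


def sample_shots(
    distribution: Mapping[str, float],
    n_shots: int,
    seed: int | np.random.Generator,
) -> MeasurementHistogram:
    """Multinomial draw of ``n_shots`` observations from an exact distribution.

    Parameters
    ----------
    distribution:
        Logical bit string -> probability; must sum to 1 (tolerance 1e-9).
    n_shots:
        Number of measurement shots (= simulated cells in joint mode, or
        cells per type in paired mode); must be >= 1.
    seed:
        Integer seed or a ``numpy.random.Generator``.  Identical seeds yield
        identical histograms.
    """
    if n_shots < 1:
        raise ValueError(f"n_shots must be >= 1, got {n_shots}")
    keys = sorted(distribution)
    probs = np.array([distribution[k] for k in keys], dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty distribution")
    if np.any(probs < 0):
        raise ValueError("negative probability in distribution")
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"distribution sums to {total}, expected 1")
    probs = probs / total

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(n_shots, probs)
    counts = {k: int(c) for k, c in zip(keys, draws) if c > 0}
    return MeasurementHistogram(counts=counts, n_shots=n_shots)
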