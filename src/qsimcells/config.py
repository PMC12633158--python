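"""Experiment configuration: a versioned, JSON-round-trippable schema."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

from .cccbench import LRPair
from .kernel import GeneSpec, Topology
from .matrixgen import NBParams

__all__ = ["ExperimentConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


class GeneConfig(BaseModel):
    name: str
    activation: float = Field(ge=0.0, le=1.0)
    cell_type: Literal["CT1", "CT2"]


class TopologiesConfig(BaseModel):
    """Ordered control-target pairs, all in global qubit indices."""

    intra_ct1: List[Tuple[int, int]] = Field(default_factory=list)
    intra_ct2: List[Tuple[int, int]] = Field(default_factory=list)
    inter: List[Tuple[int, int]] = Field(default_factory=list)


class NBConfig(BaseModel):
    mu: float = Field(default=5.0, gt=0)
    r: float = Field(default=1.0, gt=0)


class HKGConfig(BaseModel):
    n: int = Field(default=50, ge=0)
    mu: float = Field(default=80.0, gt=0)
    r: float = Field(default=6.0, gt=0)


class PreprocessingConfig(BaseModel):
    target_sum: float = Field(default=10_000.0, gt=0)
    log1p: bool = True
    scale: bool = True
    corr_threshold: float = Field(default=0.5, gt=0, lt=1)


class LRPairConfig(BaseModel):
    ligand: str
    receptor: str
    sender: Literal["CT1", "CT2"]
    receiver: Literal["CT1", "CT2"]
    annotation: Literal["true_mechanistic", "false_control"] = "true_mechanistic"
    name: str = ""
    pathway: str = ""


class ExperimentConfig(BaseModel):
    """Full description of one simulation + benchmarking run."""

    schema_version: int = SCHEMA_VERSION
    name: str = "experiment"
    genes: List[GeneConfig]
    topologies: TopologiesConfig = Field(default_factory=TopologiesConfig)
    shots: int = Field(default=2000, ge=1)
    seed: int = 0
    nb: NBConfig = Field(default_factory=NBConfig)
    hkg: HKGConfig = Field(default_factory=HKGConfig)
    split_mode: Literal["paired", "joint"] = "paired"
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    lr_pairs: List[LRPairConfig] = Field(default_factory=list)

    @field_validator("schema_version")
    @classmethod
    def _known_schema(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}")
        return v

    @model_validator(mode="after")
    def _validate_structure(self) -> "ExperimentConfig":
        if not self.genes:
            raise ValueError("at least one gene is required")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        types = [g.cell_type for g in self.genes]
        # CT1 block must precede CT2 block (global index = list position)
        if "CT2" in types and "CT1" in types:
            first_ct2 = types.index("CT2")
            if any(t == "CT1" for t in types[first_ct2:]):
                raise ValueError("genes must list the CT1 register first, then CT2")
        n = len(self.genes)
        for label, pairs in (
            ("intra_ct1", self.topologies.intra_ct1),
            ("intra_ct2", self.topologies.intra_ct2),
            ("inter", self.topologies.inter),
        ):
            for c, t in pairs:
                if c == t:
                    raise ValueError(f"{label}: control == target ({c})")
                if not (0 <= c < n and 0 <= t < n):
                    raise ValueError(f"{label}: pair ({c}, {t}) outside 0..{n - 1}")
        for p in self.lr_pairs:
            if p.ligand not in names or p.receptor not in names:
                raise ValueError(f"LR pair {p.ligand}->{p.receptor}: unknown gene")
        return self

    # -- conversions into the domain types used by the compute modules -----

    def gene_specs(self) -> List[GeneSpec]:
        specs = []
        local = {"CT1": 0, "CT2": 0}
        for i, g in enumerate(self.genes):
            specs.append(
                GeneSpec(
                    name=g.name,
                    activation=g.activation,
                    cell_type=g.cell_type,
                    global_index=i,
                    local_index=local[g.cell_type],
                )
            )
            local[g.cell_type] += 1
        return specs

    def topology_sequence(self) -> List[Topology]:
        """Application order: intra-CT1, intra-CT2, then inter-register."""
        seq = []
        if self.topologies.intra_ct1:
            seq.append(Topology(tuple(self.topologies.intra_ct1), scope="intra"))
        if self.topologies.intra_ct2:
            seq.append(Topology(tuple(self.topologies.intra_ct2), scope="intra"))
        if self.topologies.inter:
            seq.append(Topology(tuple(self.topologies.inter), scope="inter"))
        return seq

    def truth_topology(self) -> Topology:
        """All programmed control-target pairs, in application order."""
        pairs = (
            tuple(self.topologies.intra_ct1)
            + tuple(self.topologies.intra_ct2)
            + tuple(self.topologies.inter)
        )
        return Topology(pairs, scope="mixed")

    def nb_params(self) -> dict:
        return {g.name: NBParams(mu=self.nb.mu, r=self.nb.r) for g in self.genes}

    def lr_pair_objects(self) -> List[LRPair]:
        return [
            LRPair(
                ligand=p.ligand,
                receptor=p.receptor,
                sender=p.sender,
                receiver=p.receiver,
                annotation=p.annotation,
                name=p.name or f"{p.ligand}_{p.receptor}",
                pathway=p.pathway,
            )
            for p in self.lr_pairs
        ]

    def preproc_config(self):
        from .netbench import PreprocConfig

        return PreprocConfig(
            target_sum=self.preprocessing.target_sum,
            log1p=self.preprocessing.log1p,
            scale=self.preprocessing.scale,
            corr_threshold=self.preprocessing.corr_threshold,
        )


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    )


def load_config(path) -> ExperimentConfig:
    return ExperimentConfig.model_validate_json(Path(path).read_text())
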