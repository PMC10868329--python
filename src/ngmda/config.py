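"""Run configuration: every tunable hyper-parameter of the model in one place.

Defaults follow the published operating point of the method: similarity
threshold ``beta`` = 0.9, ``walk_steps`` = 2 random-walk steps, two layers
each for neighbor feature fusion (NFF) and whole-graph feature fusion
(GFF), position/topology balance ``tau`` = 0.4 and loss balance
``epsilon`` = 0.2.  Embedding width, head counts, the pair-head width and
the training schedule are engineering choices exposed here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # graph construction
    beta: float = 0.9
    walk_steps: int = 2
    binarize_adjacency: bool = False
    # embedding enhancement
    embed_dim: int = 64
    enc_layers: int = 2
    dec_layers: int = 2
    # neighbor feature fusion
    nff_layers: int = 2
    nff_heads: int = 4
    tau: float = 0.4
    share_channel_attention: bool = False
    # whole-graph feature fusion
    gff_layers: int = 2
    gff_heads: int = 4
    # prediction head and optimization
    head_dim: int = 64
    epsilon: float = 0.2
    lr: float = 1e-3
    epochs: int = 80
    seed: int = 0
    # ablation switches
    disable_es: bool = False
    disable_nff: bool = False
    disable_gff: bool = False
    disable_topo: bool = False
    disable_posi: bool = False
    disable_rel: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.walk_steps < 1:
            raise ValueError("walk_steps must be >= 1")
        for name in ("embed_dim", "enc_layers", "dec_layers", "nff_layers",
                     "nff_heads", "gff_layers", "gff_heads", "head_dim", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.embed_dim % self.gff_heads != 0:
            raise ValueError("embed_dim must be divisible by gff_heads")
        if self.lr <= 0:
            raise ValueError("lr must be positive")

    # effective tau after the position/topology ablation switches
    @property
    def effective_tau(self) -> float:
        if self.disable_topo and self.disable_posi:
            raise ValueError("cannot disable both position and topology channels")
        if self.disable_topo:
            return 1.0
        if self.disable_posi:
            return 0.0
        return self.tau

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        return cls.from_dict(values)

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
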