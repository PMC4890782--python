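"""Run configuration: flat key-value (YAML) with validated defaults.

Defaults are the calibrated model settings: eps_B = -0.37 with
eps_A = 0.96 eps_B, well width 0.5 A, 6.0 A inclusive contact cutoff with
sequence separation >= 3, 100x100 landscape grid, 30% burn-in, exchange
attempts every 5000 cycles, k = 50 clusters with a 5.75 A centroid-graph
threshold and eps_pipi = 1.5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # chain / structures
    sequence: str = ""
    structures_A: list[str] = field(default_factory=list)
    structures_B: list[str] = field(default_factory=list)
    fixture_length: int = 0          # > 0: synthetic two-fold fixture system
    # contact map
    cutoff: float = 6.0
    min_seq_sep: int = 3
    gly_policy: str = "calpha"
    # SBM
    eps_B: float = -0.37
    eps_ratio: float = 0.96
    w: float = 0.5
    # transferable component
    transferable_model: str = "none"   # none | standin
    # sampling
    n_replicas: int = 4
    t_min: float = 0.5
    t_max: float = 2.0
    n_cycles: int = 2000
    exchange_interval: int = 5000
    record_stride: int = 10
    seed: int = 0
    # analysis
    burn_in: float = 0.30
    grid: int = 100
    k_clusters: int = 50
    graph_threshold: float = 5.75
    eps_pipi: float = 1.5

    def validate(self) -> "RunConfig":
        if not self.sequence and self.fixture_length <= 0:
            raise ValueError("config needs a sequence or a fixture_length")
        if self.fixture_length <= 0 and not (self.structures_A and self.structures_B):
            raise ValueError("config needs structure paths for both folds "
                             "(or a fixture_length)")
        if self.gly_policy not in ("calpha", "none"):
            raise ValueError(f"unknown gly_policy {self.gly_policy!r}")
        if self.transferable_model not in ("none", "standin"):
            raise ValueError(f"unknown transferable_model {self.transferable_model!r}")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")
        if self.n_replicas < 2 or self.n_cycles < 1:
            raise ValueError("need >= 2 replicas and >= 1 cycle")
        return self

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"config_hash={self.hash()} seed={self.seed}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
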