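"""Pipeline configuration: one dataclass holding every tunable, loadable
from YAML with strict key checking. The seed is mandatory because every
stochastic step (imputation draws, label permutations, simulations) derives
its randomness from it."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int
    min_fraction: float = 0.7
    n_perm: int = 250
    fdr: float = 0.05
    alpha: float = 0.05
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    n_belts: int = 11
    threshold_method: str | float = "otsu"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for stochastic steps")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr and alpha must be in (0, 1)")
        if self.n_belts < 1:
            raise ValueError("n_belts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in payload:
            raise ValueError("config must set a seed")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
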