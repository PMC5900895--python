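"""Run configuration: structured-text (YAML) files with full defaulting.

Command-line flags override config-file values; config-file values
override the defaults below.  All randomness of a run flows from the one
``seed`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .evaluation import STRATEGIES, EvalConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Operational settings of a pipeline run."""

    cohort_dir: str | None = None
    template_dir: str | None = None
    output_dir: str = "out"
    grid_size: int = 64
    voxel_mm: float = 2.0
    max_order: int = 2
    strategies: tuple = STRATEGIES
    seed: int = 0
    n_random: int = 100
    qc_threshold: float = 0.90
    use_registration: bool = False

    def __post_init__(self):
        if not (0.0 < self.qc_threshold <= 1.0):
            raise ConfigurationError(
                f"qc_threshold must be in (0, 1], got {self.qc_threshold}")
        if self.max_order not in (1, 2, 3):
            raise ConfigurationError(
                f"max_order must be 1, 2 or 3, got {self.max_order}")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ConfigurationError(f"unknown strategies: {sorted(unknown)}")
        object.__setattr__(self, "strategies", tuple(self.strategies))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (non-None) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(
                f"{path}: unknown config keys: {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["strategies"] = list(self.strategies)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def eval_config(self) -> EvalConfig:
        return EvalConfig(max_order=self.max_order, n_random=self.n_random,
                          seed=self.seed, strategies=tuple(self.strategies),
                          use_registration=self.use_registration)
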