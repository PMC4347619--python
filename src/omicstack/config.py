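"""Pipeline configuration: documented defaults, YAML round-trip, resolution.

Every field has a default; the fully-default configuration generates the
bundled synthetic demo and runs it end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .integration import STRATEGIES
from .synth import SyntheticConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # data: either three TSV paths, or None to generate synthetically
    gep_path: str | None = None
    dmp_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    allow_subset: bool = False
    # strategies and cross-validation
    strategies: list[str] = field(default_factory=lambda: list(STRATEGIES))
    k_outer: int = 5
    k_inner: int = 5
    # lasso path
    grid_size: int = 50
    grid_ratio: float = 1e-3
    tol: float = 1e-7
    nmc_posteriors: str = "in_sample"  # or "out_of_fold"
    # global association test
    run_global_test: bool = True
    n_permutations: int = 10_000
    # run control
    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig.from_dict(self.synthetic)
        if isinstance(self.strategies, str):
            self.strategies = (
                list(STRATEGIES) if self.strategies == "all" else self.strategies.split(",")
            )
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}; expected {STRATEGIES} or 'all'")
        paths = (self.gep_path, self.dmp_path, self.labels_path)
        if any(paths) and not all(paths):
            raise ValueError("gep_path, dmp_path and labels_path must be given together")
        if self.nmc_posteriors not in ("in_sample", "out_of_fold"):
            raise ValueError("nmc_posteriors must be 'in_sample' or 'out_of_fold'")

    @property
    def uses_synthetic_data(self) -> bool:
        return self.gep_path is None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)
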