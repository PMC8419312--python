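"""Pipeline configuration: YAML-serializable run parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import yaml

from .connectivity import default_density_grid
from .synthetic import SyntheticCohortSpec


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialized into every results directory."""

    input_dir: str | None = None
    output_dir: str = "results"
    density_min: float = 0.10
    density_max: float = 0.50
    density_step: float = 0.01
    n_nulls: int = 100
    n_swap_per_edge: int = 10
    centrality: str = "degree"
    test_kind: str = "t"
    alpha: float = 0.05
    seed: int = 0
    synthetic: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.density_min < self.density_max <= 1):
            raise ValueError("need 0 < density_min < density_max <= 1")
        if self.density_step <= 0:
            raise ValueError("density_step must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_nulls < 1 or self.n_swap_per_edge < 1:
            raise ValueError("n_nulls and n_swap_per_edge must be >= 1")

    @property
    def densities(self):
        return default_density_grid(
            self.density_min, self.density_max, self.density_step
        )

    def synthetic_spec(self) -> SyntheticCohortSpec:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        return SyntheticCohortSpec(**block)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
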