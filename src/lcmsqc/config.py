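"""Pipeline configuration: a YAML-serializable bundle of thresholds and seeds."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need, round-trippable through YAML."""

    ion_mode: str = "positive"
    seed: int = 0
    cv_max: float = 0.30
    min_mean_qc: float | None = None
    span_policy: str = "optimize"  # or a float encoded as string
    span_grid: tuple[float, ...] = (0.3, 0.45, 0.6, 0.75, 0.9, 1.0)
    eic_tol_ppm: float = 20.0
    rt_half_window: float = 0.1
    linearity_tolerance: float = 0.10
    reference_weight_mg: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.cv_max <= 1:
            raise ValueError("cv_max must be in (0, 1]")
        if self.min_mean_qc is not None and self.min_mean_qc < 0:
            raise ValueError("min_mean_qc must be >= 0")
        if not 0 < self.linearity_tolerance < 1:
            raise ValueError("linearity_tolerance must be in (0, 1)")
        if self.eic_tol_ppm <= 0 or self.rt_half_window <= 0:
            raise ValueError("EIC tolerances must be positive")
        self.span_grid = tuple(float(s) for s in self.span_grid)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration (recorded in output sidecars)."""
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_info(config: PipelineConfig, stage: str) -> dict:
    from . import __version__

    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.digest(),
        "lcmsqc_version": __version__,
    }
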