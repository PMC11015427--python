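"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """Calibration constants and paths shared by the pipeline stages.

    Defaults follow the study protocol: 75/25 presence split, >= 10,000
    background points, a 5000-iteration cap on the MaxEnt optimiser, and the
    ecoclimatic-index class thresholds (0.2, 0.5).
    """

    # inputs / outputs
    stack_dir: Optional[str] = None
    occurrences: Optional[str] = None
    out_dir: str = "results"
    # calibration
    train_fraction: float = 0.75
    n_background: int = 10000
    max_iter: int = 5000
    beta_scale: float = 0.05
    bioclim_mode: str = "percentile"
    ei_thresholds: tuple[float, float] = (0.2, 0.5)
    overlap_method: str = "min"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        self.ei_thresholds = tuple(self.ei_thresholds)  # type: ignore[assignment]
        t1, t2 = self.ei_thresholds
        if not t1 < t2:
            raise ValueError("ei_thresholds must be strictly increasing")
        if self.bioclim_mode not in ("percentile", "meansd"):
            raise ValueError("bioclim_mode must be percentile or meansd")
        if self.overlap_method not in ("min", "binary", "subtract"):
            raise ValueError("overlap_method must be min, binary or subtract")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ei_thresholds"] = list(self.ei_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kw) -> "PipelineConfig":
        """Flag overrides win over file values; None overrides are ignored."""
        d = self.to_dict()
        d.update({k: v for k, v in kw.items() if v is not None})
        return PipelineConfig.from_dict(d)
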