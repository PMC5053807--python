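"""Run configuration: one serializable object drives every pipeline stage.

Every stochastic stage has its own explicit seed; there are no hidden
defaults — the configuration that actually ran, defaults materialized, is
written into the dataset manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]

REQUIRED_SEEDS = ("design", "behavior", "volumes", "shuffles", "flips")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a simulated cohort and its analysis."""

    seeds: dict = field(
        default_factory=lambda: {"design": 1, "behavior": 2, "volumes": 3, "shuffles": 4, "flips": 5}
    )
    n_subjects: int = 26
    n_shuffles: int = 10_000
    n_flips: int = 10_000
    models: list = field(
        default_factory=lambda: [
            "spatial",
            "temporal",
            "combined",
            "temporal_without_spatial",
            "spatial_without_temporal",
        ]
    )
    rois: list = field(default_factory=lambda: ["effect", "control"])
    roi_mask_paths: dict = field(default_factory=dict)   # name -> NIfTI path (overrides built-ins)
    grid_shape: list = field(default_factory=lambda: [16, 16, 16])
    voxel_size: list = field(default_factory=lambda: [1.5, 1.5, 1.5])
    effect_size: float = -0.6
    noise_sd: float = 1.0
    tail: str = "negative"
    searchlight_radius: float = 9.0
    searchlight_min_voxels: int = 30
    run_searchlight: bool = False
    out_dir: str = "eventmap_run"

    def validate(self) -> "RunConfig":
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ConfigError(f"missing seeds: {missing}")
        for k, v in self.seeds.items():
            if not isinstance(v, int):
                raise ConfigError(f"seed {k!r} must be an integer, got {v!r}")
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        if self.tail not in ("negative", "positive"):
            raise ConfigError("tail must be 'negative' or 'positive'")
        if not (-1.0 <= self.effect_size <= 0.0):
            raise ConfigError("effect_size must lie in [-1, 0]")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
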