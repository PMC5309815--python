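"""Validated run configuration for the end-to-end pipeline.

The configuration is a strict schema: unknown keys anywhere are rejected
before any computation starts, so typos cannot silently fall back to
defaults.  Every block mirrors the parameters of one pipeline stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .synthetic import SimulationConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationBlock(_Strict):
    channel: str = "nuclear"
    smoothing_sigma_um: float = 4.0
    threshold_rule: str = "otsu"
    k: float = 5.0
    min_nodule_volume_mm3: float = 2e-5
    connectivity: int = 26
    fill_holes: bool = True


class DetectionBlock(_Strict):
    channel: str = "tam_np"
    cell_radius_um: float = 5.0
    threshold_k: float = 6.0
    min_separation_um: float | None = None


class WidefieldBlock(_Strict):
    enabled: bool = True
    downsample_factor: int = 4
    blur_sigma_um: float = 10.0
    calibration_mode: str = "through_origin"


class ProfileBlock(_Strict):
    enabled: bool = True
    channel: str = "tam_np"
    n_rays: int = 36
    n_bins: int = 10


class ColocalizationBlock(_Strict):
    enabled: bool = True
    channel_a: str = "tam_np"
    channel_b: str = "tumor_reporter"
    method: str = "pearson"


class RunConfig(_Strict):
    """Top-level configuration: either simulate a field (default) or read an
    existing volume, then segment, detect, quantify, calibrate, profile and
    colocalize, writing all tables under ``out_dir``."""

    seed: int = 0
    out_dir: Path = Path("results/run")
    input_volume: Path | None = None
    simulation: dict = {}
    segmentation: SegmentationBlock = SegmentationBlock()
    detection: DetectionBlock = DetectionBlock()
    widefield: WidefieldBlock = WidefieldBlock()
    profile: ProfileBlock = ProfileBlock()
    colocalization: ColocalizationBlock = ColocalizationBlock()
    log_level: str = "INFO"

    @field_validator("simulation")
    @classmethod
    def _no_seed_in_simulation(cls, v: dict) -> dict:
        if "seed" in v:
            raise ValueError("set the top-level 'seed', not simulation.seed")
        return v

    @model_validator(mode="after")
    def _validate_simulation(self) -> "RunConfig":
        if self.input_volume is None:
            try:
                self.simulation_config()  # full dataclass validation
            except TypeError as e:  # unknown key
                raise ValueError(f"invalid simulation block: {e}") from e
        return self

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(**self.simulation, seed=self.seed)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (where outputs land and how
        verbosely we log do not change the science)."""
        payload = json.loads(self.model_dump_json(exclude={"out_dir", "log_level"}))
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)
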