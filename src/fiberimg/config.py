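"""Structured run configuration with hardware defaults.

The default configuration mirrors the reference hardware operating point:
1064 nm source with 0.14 nm bandwidth, 45.1 ps pulses at a 65 ns period,
a 50 um-core NA 0.22 step-index fiber of 1 km, a 30 GHz detector with a
15 ps impulse response sampled at 100 GS/s, and 7.56 um object pixels.
Unknown keys are rejected; configs hash to a stable digest for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .decoder import DecoderConfig
from .encoder import DetectorSpec, OpticalPulse, SceneGeometry
from .fiber import FiberSpec

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FiberBlock(_Block):
    core_radius_um: float = 25.0
    na: float = 0.22
    n_clad: float = 1.4496
    length_m: float = 1000.0
    wavelength_nm: float = 1064.0

    def to_spec(self) -> FiberSpec:
        return FiberSpec(**self.model_dump())


class PulseBlock(_Block):
    fwhm_ps: float = 45.1
    period_ns: float = 65.0
    bandwidth_nm: float = 0.14
    energy: float = 1.0

    def to_spec(self) -> OpticalPulse:
        return OpticalPulse(fwhm_ps=self.fwhm_ps, period_ns=self.period_ns, energy=self.energy)


class DetectorBlock(_Block):
    bandwidth_ghz: float = 30.0
    sample_rate_gsps: float = 100.0
    noise_snr_db: float = 30.0
    impulse_fwhm_ps: float = 15.0

    def to_spec(self) -> DetectorSpec:
        return DetectorSpec(**self.model_dump())


class GeometryBlock(_Block):
    pixel_pitch_um: float = 7.56
    image_shape: tuple[int, int] = (28, 28)
    magnification: float = 0.24
    offset_um: tuple[float, float] = (2.0, 3.0)

    def to_spec(self) -> SceneGeometry:
        d = self.model_dump()
        d["image_shape"] = tuple(d["image_shape"])
        d["offset_um"] = tuple(d["offset_um"])
        return SceneGeometry(**d)


class DecoderBlock(_Block):
    arch: str = "fc5"
    input_len: int = 4096
    output_shape: tuple[int, int] = (64, 64)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "mse"
    ridge_lambda: float = 1e-2
    unet_base_channels: int = 8

    def to_spec(self) -> DecoderConfig:
        d = self.model_dump()
        d["output_shape"] = tuple(d["output_shape"])
        return DecoderConfig(**d)


class StudyBlock(_Block):
    n_train: int = 2000
    n_test: int = 500
    n_classes: int = 10
    lengths_m: list[float] = Field(
        default_factory=lambda: [100.0, 150.0, 250.0, 400.0, 700.0, 1000.0]
    )
    strengths: list[float] = Field(default_factory=lambda: [0.0, 0.1, 0.2, 0.4, 0.6, 0.8])
    delay_jitter_ps: float = 30.0
    coupling_model: str = "coherent"


class RunConfig(_Block):
    """Top-level configuration: one block per subsystem plus the run seed."""

    fiber: FiberBlock = Field(default_factory=FiberBlock)
    pulse: PulseBlock = Field(default_factory=PulseBlock)
    detector: DetectorBlock = Field(default_factory=DetectorBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    decoder: DecoderBlock = Field(default_factory=DecoderBlock)
    study: StudyBlock = Field(default_factory=StudyBlock)
    seed: int = 0
    version: str = "1"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing keys take defaults.

    An empty (or absent) file yields the full default configuration.
    Unknown keys raise a validation error naming the offending fields.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short digest of the config, independent of key order."""
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
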