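"""Run configuration: schema, validation, YAML/JSON loading.

Every command-line run is driven by one validated :class:`RunConfig`;
the resolved config is written next to the outputs so any run can be
reproduced from its output directory plus the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class AcquisitionBlock(BaseModel):
    wavelengths: list[float] = [665.0, 860.0]
    fx: float = 0.2  # patterned spatial frequency, mm^-1
    phases: list[float] = [0.0, 2 * np.pi / 3, 4 * np.pi / 3]
    pixel_pitch: float = 150.0 / 1024.0  # mm
    bit_depth: int = 16
    dc_level: float = 30000.0
    modulation_depth: float = 0.8

    @field_validator("fx")
    @classmethod
    def _fx_nonneg(cls, v):
        if v <= 0:
            raise ValueError("fx must be > 0")
        return v

    @model_validator(mode="after")
    def _nyquist(self):
        if self.fx * self.pixel_pitch >= 0.5:
            raise ValueError(
                f"fx={self.fx} at pitch {self.pixel_pitch} violates Nyquist")
        return self


class LutBlock(BaseModel):
    mu_a_range: tuple[float, float] = (0.005, 0.05)
    mu_s_prime_range: tuple[float, float] = (0.5, 3.0)
    grid_sizes: tuple[int, int] = (64, 64)
    engine: str = "diffusion"
    n_tissue: float = 1.4
    n_photons: int = 10000  # monte-carlo engine only

    @model_validator(mode="after")
    def _ranges(self):
        for rng, name in ((self.mu_a_range, "mu_a_range"),
                          (self.mu_s_prime_range, "mu_s_prime_range")):
            if not 0 < rng[0] < rng[1]:
                raise ValueError(f"{name} must be positive and ordered")
        if self.engine not in ("diffusion", "monte-carlo"):
            raise ValueError(f"unknown LUT engine {self.engine!r}")
        if self.n_tissue < 1:
            raise ValueError("n_tissue must be >= 1")
        return self


class FilterBlock(BaseModel):
    dc_cutoff_frac: float = 0.5
    ac_halfwidth_frac: float = 0.5
    window: str = "blackman"
    support_periods: float = 6.0
    padding: str = "reflect"


class PhantomBlock(BaseModel):
    # wavelength -> {mu_a, mu_s_prime}; the silicone reference phantom
    properties: dict[float, dict[str, float]] = {
        665.0: {"mu_a": 0.01, "mu_s_prime": 1.1},
        860.0: {"mu_a": 0.02, "mu_s_prime": 0.8},
    }

    @model_validator(mode="after")
    def _positive(self):
        for wl, p in self.properties.items():
            if p.get("mu_a", 0) <= 0 or p.get("mu_s_prime", 0) <= 0:
                raise ValueError(f"phantom properties at {wl} nm must be > 0")
        return self


class SceneBlock(BaseModel):
    shape: tuple[int, int] = (1024, 1280)
    roi_sto2: tuple[float, float, float] = (0.3008, 0.4567, 0.4808)
    thb: float = 60.0
    mu_s_prime: dict[float, float] = {665.0: 1.3, 860.0: 1.0}
    gradient_width_mm: float = 5.0
    loop_height_mm: float = 30.0

    @model_validator(mode="after")
    def _check(self):
        if not all(0 <= v <= 1 for v in self.roi_sto2):
            raise ValueError("roi_sto2 values must lie in [0, 1]")
        if self.thb <= 0:
            raise ValueError("thb must be > 0")
        return self


class NoiseBlock(BaseModel):
    read_sd: float = 2.0
    shot: bool = True


class RunConfig(BaseModel):
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    lut: LutBlock = Field(default_factory=LutBlock)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    scene: SceneBlock = Field(default_factory=SceneBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    mode: str = "ssop"  # or "sfdi"
    seed: int = 0

    @model_validator(mode="after")
    def _mode(self):
        if self.mode not in ("ssop", "sfdi"):
            raise ValueError(f"mode must be 'ssop' or 'sfdi', got {self.mode}")
        if not all(w in self.phantom.properties
                   for w in self.acquisition.wavelengths):
            raise ValueError("phantom must cover every acquisition wavelength")
        return self

    @property
    def fx_pair(self) -> tuple[float, float]:
        return (0.0, self.acquisition.fx)

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def write_resolved(self, path: Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            yaml.safe_dump(self.resolved_dict(), fh, sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config; defaults when ``None``.

    Raises ConfigError (exit code 2 at the CLI) on any schema violation.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = json.loads(text) if path.suffix == ".json" \
            else yaml.safe_load(text)
        return RunConfig.model_validate(data or {})
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
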