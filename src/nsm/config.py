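"""YAML run configuration with strict schema validation.

A run config describes one end-to-end scenario: the channel, the species
present, the optical model, the hydrodynamic context, the simulation plan
and the tracking/inference parameters.  Unknown keys are rejected so typos
fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import ChannelGeometry, get_channel
from .hydro import HydroContext
from .optics import OpticalModel
from .simulate import DNA_KDA_PER_BP, SimulationPlan, SpeciesSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsConfig(_Strict):
    n_medium: float = 1.33
    n_wall: float = 1.46
    a: float = 4.6e-4
    psf_sigma: float = 100.0
    pixel_pitch: float = 30.0
    noise_rel: float = 5e-5
    frame_rate: float = 200.0

    def to_model(self) -> OpticalModel:
        return OpticalModel(**self.model_dump())


class HydroConfig(_Strict):
    temperature: float = 294.15
    viscosity: float = 9.78e-4

    def to_model(self) -> HydroContext:
        return HydroContext(**self.model_dump())


class ChannelConfig(_Strict):
    name: str | None = None  # named channel I-VI, or explicit dimensions
    width_nm: float | None = None
    height_nm: float | None = None
    fov_length_nm: float = 15_000.0

    @model_validator(mode="after")
    def _check(self) -> "ChannelConfig":
        if self.name is None and (self.width_nm is None or self.height_nm is None):
            raise ValueError("channel needs either a name or width_nm+height_nm")
        return self

    def to_model(self) -> ChannelGeometry:
        if self.name is not None:
            return get_channel(self.name, self.fov_length_nm)
        return ChannelGeometry(self.width_nm, self.height_nm, self.fov_length_nm)


class SpeciesConfig(_Strict):
    name: str
    mw_kda: float | None = None
    basepairs: int | None = None  # DNA shortcut: MW = 0.650 kDa/bp
    rs_nm: float | None = None
    concentration: float | None = None
    drift_velocity: float = 0.0
    d_um2_s: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "SpeciesConfig":
        if (self.mw_kda is None) == (self.basepairs is None):
            raise ValueError("species needs exactly one of mw_kda or basepairs")
        return self

    def to_model(self) -> SpeciesSpec:
        mw = self.mw_kda if self.mw_kda is not None else DNA_KDA_PER_BP * self.basepairs
        return SpeciesSpec(
            name=self.name,
            mw_kda=mw,
            rs_nm=self.rs_nm,
            concentration=self.concentration,
            drift_velocity=self.drift_velocity,
            d_um2_s=self.d_um2_s,
        )


class PlanConfig(_Strict):
    n_frames: int = 500
    substeps_per_frame: int = 20
    domain_length_nm: float | None = None
    contrast_jitter: float = 0.0
    n_scenes: int = 1  # independent repeats, trajectories pooled

    def to_model(self, channel: ChannelGeometry, dt: float, seed: int) -> SimulationPlan:
        return SimulationPlan(
            channel=channel,
            dt=dt,
            n_frames=self.n_frames,
            substeps_per_frame=self.substeps_per_frame,
            domain_length_nm=self.domain_length_nm,
            rng_seed=seed,
            contrast_jitter=self.contrast_jitter,
        )


class TrackConfig(_Strict):
    kappa: float = 5.0
    ioc_halfwidth_nm: float = 800.0
    template_sigma_nm: float | None = None  # default: PSF + motion blur
    gate_nm: float | None = None  # default: diffusion-scaled from the species
    d_max_um2_s: float = 30.0  # gate fallback when no species declared
    gap_frames: int = 3
    min_n: int = 50
    immobile_window: int = 50
    immobile_sigma_factor: float = 3.0
    flow: bool | None = None  # default: on iff any species drifts


class InferConfig(_Strict):
    field: str = "mw_kda"
    n_components: int = 1
    bin_width: float | None = None


class RunConfig(_Strict):
    channel: ChannelConfig
    species: list[SpeciesConfig] = Field(min_length=1)
    optics: OpticsConfig = OpticsConfig()
    hydro: HydroConfig = HydroConfig()
    plan: PlanConfig = PlanConfig()
    track: TrackConfig = TrackConfig()
    infer: InferConfig = InferConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
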