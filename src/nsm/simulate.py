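"""Forward model: Brownian molecules in a nanochannel rendered to kymographs.

The generator produces ground-truthed synthetic data under the reference
experimental conditions: 1-D overdamped Brownian motion (optionally with
drift) at the hindered diffusivity set by the channel, rendered as
negative-contrast Gaussian dips whose integral equals the species' iOC,
with motion blur (substep averaging within the exposure), pixelation and
additive relative contrast noise of 5e-5 per pixel at 200 fps.

Boundary conditions are reflecting at the ends of the simulation domain
(default twice the field of view, centered), while the field of view itself
is open: molecules freely enter and leave the rendered region, as in the
experiment.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry
from .hydro import HydroContext, expected_count, globular_radius_from_mw, hindered_diffusivity
from .kymograph import Kymograph
from .optics import OpticalModel, ioc_from_mw

__all__ = [
    "SpeciesSpec",
    "BindingEvent",
    "SimulationPlan",
    "MoleculeTruth",
    "GroundTruth",
    "simulate_trajectory",
    "render_kymograph",
    "simulate_experiment",
    "raw_from_contrast",
    "DNA_KDA_PER_BP",
]

#: double-stranded DNA mass per base pair, kDa
DNA_KDA_PER_BP = 0.650


@dataclass(frozen=True)
class SpeciesSpec:
    """A molecular species to simulate.

    ``mw_kda`` sets the optical contrast; ``rs_nm`` the diffusivity (derived
    from the globular scaling when omitted).  ``concentration`` (mol/L), when
    given, drives Poisson occupancy sampling; otherwise exactly one copy is
    placed.  ``drift_velocity`` (nm/s) models pressure-driven flow.
    """

    name: str
    mw_kda: float
    rs_nm: float | None = None
    concentration: float | None = None
    drift_velocity: float = 0.0
    d_um2_s: float | None = None  # explicit diffusivity override (um^2/s)

    def __post_init__(self) -> None:
        if self.mw_kda < 0:
            raise ValueError("mw_kda must be non-negative")
        if self.rs_nm is not None and self.rs_nm <= 0:
            raise ValueError("rs_nm must be positive")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.d_um2_s is not None and self.d_um2_s < 0:
            raise ValueError("d_um2_s must be non-negative")

    @property
    def radius_nm(self) -> float:
        """Hydrodynamic radius: explicit, or globular b*MW^(1/3) fallback."""
        if self.rs_nm is not None:
            return self.rs_nm
        return globular_radius_from_mw(self.mw_kda)

    @classmethod
    def dna(
        cls, basepairs: int, rs_nm: float, name: str | None = None, **kw
    ) -> "SpeciesSpec":
        """Double-stranded DNA of ``basepairs`` bp: MW = 0.650 kDa per bp."""
        if basepairs < 0:
            raise ValueError("basepairs must be non-negative")
        return cls(
            name=name or f"{basepairs}bp DNA",
            mw_kda=DNA_KDA_PER_BP * basepairs,
            rs_nm=rs_nm,
            **kw,
        )


@dataclass(frozen=True)
class BindingEvent:
    """Transient immobilization: the molecule freezes for a frame interval.

    ``position_nm``, when given, relocates the molecule to that wall site at
    the start of the event; otherwise it freezes in place.
    """

    start_frame: int
    duration_frames: int
    position_nm: float | None = None
    molecule: int = 0


@dataclass(frozen=True)
class SimulationPlan:
    """Scene layout and discretization of a simulated recording."""

    channel: ChannelGeometry
    dt: float = 0.005
    n_frames: int = 500
    substeps_per_frame: int = 20
    domain_length_nm: float | None = None  # default: 2 x FOV, centered
    rng_seed: int = 0
    binding_events: tuple[BindingEvent, ...] = ()
    contrast_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")
        if (
            self.domain_length_nm is not None
            and self.domain_length_nm < self.channel.fov_length_nm
        ):
            raise ValueError("domain_length_nm must be >= fov_length_nm")

    @property
    def domain_nm(self) -> float:
        if self.domain_length_nm is not None:
            return self.domain_length_nm
        return 2.0 * self.channel.fov_length_nm

    @property
    def domain_bounds(self) -> tuple[float, float]:
        """Reflecting-wall coordinates (nm); FOV spans [0, fov_length]."""
        fov = self.channel.fov_length_nm
        pad = (self.domain_nm - fov) / 2.0
        return -pad, fov + pad


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unconstrained path into [lo, hi] (method of images)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.minimum(y, 2.0 * span - y)


def simulate_trajectory(
    species: SpeciesSpec,
    plan: SimulationPlan,
    ctx: HydroContext | None = None,
    rng: np.random.Generator | None = None,
    x0: float | None = None,
    binding_events: Sequence[BindingEvent] | None = None,
) -> np.ndarray:
    """Simulate one molecule; returns substep positions (n_frames, substeps).

    Each substep advances x by v*dt_sub + sqrt(2 D dt_sub) * xi with D the
    hindered diffusivity of the species in this channel; the path is folded
    back at the reflecting domain walls.  During a binding event the
    position is frozen (optionally snapped to the event's wall site).
    """
    ctx = _channel_ctx(ctx, plan.channel)
    rng = rng if rng is not None else np.random.default_rng(plan.rng_seed)
    if binding_events is None:
        binding_events = plan.binding_events
    D_nm2_s = _species_diffusivity(species, ctx) * 1e18  # m^2/s -> nm^2/s
    S = plan.substeps_per_frame
    n_steps = plan.n_frames * S
    dt_sub = plan.dt / S
    lo, hi = plan.domain_bounds
    if x0 is None:
        x0 = rng.uniform(lo, hi)

    steps = species.drift_velocity * dt_sub + math.sqrt(
        2.0 * D_nm2_s * dt_sub
    ) * rng.standard_normal(n_steps)

    events = sorted(binding_events, key=lambda e: e.start_frame)
    for ev in events:
        s0 = max(ev.start_frame * S, 0)
        s1 = min((ev.start_frame + ev.duration_frames) * S, n_steps)
        if s0 < s1:
            steps[s0:s1] = 0.0

    path = x0 + np.cumsum(steps)
    for ev in events:
        if ev.position_nm is None:
            continue
        s0 = ev.start_frame * S
        if 0 <= s0 < n_steps:
            path[s0:] += ev.position_nm - path[s0]
    return _reflect(path, lo, hi).reshape(plan.n_frames, S)


def _species_diffusivity(species: SpeciesSpec, ctx: HydroContext) -> float:
    """Diffusivity in m^2/s: explicit override, or hindered Stokes-Einstein."""
    if species.d_um2_s is not None:
        return species.d_um2_s * 1e-12
    return hindered_diffusivity(species.radius_nm, ctx)


def _channel_ctx(ctx: HydroContext | None, channel: ChannelGeometry) -> HydroContext:
    """Bind the hydro context to the channel's equivalent radius."""
    base = ctx if ctx is not None else HydroContext()
    return dataclasses.replace(
        base, equivalent_radius_nm=channel.equivalent_radius_nm
    )


@dataclass
class MoleculeTruth:
    """Ground truth for one simulated molecule."""

    molecule_id: int
    species: str
    mw_kda: float
    rs_nm: float
    D_m2_s: float
    ioc_nm: float
    positions: np.ndarray  # (n_frames, substeps)
    bound: np.ndarray  # (n_frames,) bool

    @property
    def frame_positions(self) -> np.ndarray:
        """Motion-blurred (substep-averaged) position per frame."""
        return self.positions.mean(axis=1)


@dataclass
class GroundTruth:
    """Per-molecule ground truth of a simulated scene."""

    molecules: list[MoleculeTruth]
    plan: SimulationPlan

    def to_frame(self) -> pd.DataFrame:
        """One row per molecule per frame (blur-averaged position)."""
        rows = []
        for m in self.molecules:
            xs = m.frame_positions
            rows.append(
                pd.DataFrame(
                    {
                        "molecule_id": m.molecule_id,
                        "frame": np.arange(len(xs)),
                        "x_nm": xs,
                        "mw_kda": m.mw_kda,
                        "rs_nm": m.rs_nm,
                        "D_um2_s": m.D_m2_s * 1e12,
                        "ioc_nm": m.ioc_nm,
                        "bound": m.bound,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=[
                    "molecule_id", "frame", "x_nm", "mw_kda",
                    "rs_nm", "D_um2_s", "ioc_nm", "bound",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def render_kymograph(
    truth: GroundTruth,
    optics: OpticalModel,
    plan: SimulationPlan | None = None,
    rng: np.random.Generator | None = None,
) -> Kymograph:
    """Render ground-truth trajectories into a noisy contrast kymograph.

    Each molecule contributes, per frame, the substep average of a Gaussian
    line profile (sigma = PSF sigma) of integral equal to its iOC; pixels
    sample the profile at their centers so that column-sum x pixel pitch
    recovers the iOC.  Zero-mean Gaussian noise of s.d. ``noise_rel`` is
    added per pixel.
    """
    plan = plan if plan is not None else truth.plan
    sigma = optics.psf_sigma
    pitch = optics.pixel_pitch
    if sigma / pitch < 2.0:
        raise ValueError(
            f"pixel pitch {pitch} nm undersamples the PSF (sigma {sigma} nm): "
            "need at least 2 pixels per sigma"
        )
    fov = plan.channel.fov_length_nm
    n_pix = int(round(fov / pitch)) + 1
    n_frames = plan.n_frames
    kymo = np.zeros((n_frames, n_pix))
    rng = rng if rng is not None else np.random.default_rng(plan.rng_seed)
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))

    for mol in truth.molecules:
        xs = mol.positions  # (n_frames, S)
        fmin = xs.min(axis=1)
        fmax = xs.max(axis=1)
        margin = 5.0 * sigma
        visible = (fmax > -margin) & (fmin < fov + margin)
        if not visible.any():
            continue
        idx = np.nonzero(visible)[0]
        base = np.floor((fmin[idx] - margin) / pitch).astype(int)
        width = int(np.ceil((fmax[idx] - fmin[idx]).max() / pitch)) + int(
            2 * margin / pitch
        ) + 2
        cols = base[:, None] + np.arange(width)[None, :]  # (F, W)
        px_x = cols * pitch
        # (F, S, W) Gaussian evaluations, averaged over substeps
        z = (px_x[:, None, :] - xs[idx][:, :, None]) / sigma
        profile = norm * np.exp(-0.5 * z * z).mean(axis=1)
        amp = mol.ioc_nm * np.ones(len(idx))
        if plan.contrast_jitter > 0:
            amp = amp * (1.0 + plan.contrast_jitter * rng.standard_normal(len(idx)))
        contrib = amp[:, None] * profile
        valid = (cols >= 0) & (cols < n_pix)
        np.add.at(kymo, (idx[:, None] * np.ones(width, int), np.clip(cols, 0, n_pix - 1)),
                  np.where(valid, contrib, 0.0))

    if optics.noise_rel > 0:
        kymo = kymo + rng.normal(0.0, optics.noise_rel, kymo.shape)

    meta = {
        "channel_area_nm2": plan.channel.area_nm2,
        "fov_length_nm": fov,
        "noise_rel": optics.noise_rel,
        "psf_sigma_nm": sigma,
        "kind": "contrast",
    }
    return Kymograph(kymo, plan.dt, pitch, 0.0, meta)


def simulate_experiment(
    species: Sequence[SpeciesSpec] | SpeciesSpec,
    plan: SimulationPlan,
    optics: OpticalModel | None = None,
    ctx: HydroContext | None = None,
    seed: int | None = None,
) -> tuple[Kymograph, GroundTruth]:
    """Simulate a full scene: sample occupancy, diffuse, render, add noise.

    Deterministic given the seed (``plan.rng_seed`` unless overridden): the
    same seed reproduces the kymograph bit for bit.  Species with a
    concentration get a Poisson-distributed number of copies with mean
    ``expected_count`` over the simulation domain; species without get one.
    """
    if isinstance(species, SpeciesSpec):
        species = [species]
    optics = optics if optics is not None else OpticalModel()
    ctx = _channel_ctx(ctx, plan.channel)
    rng = np.random.default_rng(seed if seed is not None else plan.rng_seed)
    lo, hi = plan.domain_bounds
    area = plan.channel.area_nm2

    molecules: list[MoleculeTruth] = []
    mol_id = 0
    bound_default = np.zeros(plan.n_frames, dtype=bool)
    for sp in species:
        if sp.concentration is not None:
            mean = expected_count(sp.concentration, area, plan.domain_nm)
            n_copies = int(rng.poisson(mean))
        else:
            n_copies = 1
        for _ in range(n_copies):
            events = tuple(
                ev for ev in plan.binding_events if ev.molecule == mol_id
            )
            x0 = rng.uniform(lo, hi)
            pos = simulate_trajectory(
                sp, plan, ctx, rng, x0=x0, binding_events=events
            )
            bound = bound_default.copy()
            for ev in events:
                bound[ev.start_frame : ev.start_frame + ev.duration_frames] = True
            molecules.append(
                MoleculeTruth(
                    molecule_id=mol_id,
                    species=sp.name,
                    mw_kda=sp.mw_kda,
                    rs_nm=sp.radius_nm,
                    D_m2_s=_species_diffusivity(sp, ctx),
                    ioc_nm=ioc_from_mw(sp.mw_kda * 1e3, area, optics),
                    positions=pos,
                    bound=bound,
                )
            )
            mol_id += 1

    truth = GroundTruth(molecules, plan)
    kymo = render_kymograph(truth, optics, plan, rng)
    kymo.metadata["rng_seed"] = seed if seed is not None else plan.rng_seed
    return kymo, truth


def raw_from_contrast(
    kymo: Kymograph,
    base_intensity: float = 1000.0,
    vignette: float = 0.2,
    gain_drift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Kymograph:
    """Emulate a raw intensity movie from a contrast kymograph.

    raw[t, x] = base * illumination(x) * gain(t) * (1 + contrast[t, x])

    with a smooth parabolic illumination vignette (peak at the center,
    relative droop ``vignette`` at the edges) and optional per-frame global
    gain jitter of relative s.d. ``gain_drift``.  Used to exercise the
    preprocessing stage on simulated data.
    """
    n_pix = kymo.n_pixels
    x = np.linspace(-1.0, 1.0, n_pix)
    illum = 1.0 - vignette * x**2
    if gain_drift > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        gain = 1.0 + gain_drift * rng.standard_normal(kymo.n_frames)
    else:
        gain = np.ones(kymo.n_frames)
    raw = base_intensity * illum[None, :] * gain[:, None] * (1.0 + kymo.contrast)
    meta = dict(kymo.metadata)
    meta["kind"] = "raw_intensity"
    return Kymograph(raw, kymo.dt, kymo.pixel_pitch, kymo.origin, meta)
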