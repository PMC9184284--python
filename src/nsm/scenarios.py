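"""Reference recovery scenarios.

Self-contained end-to-end validation runs at the instrument's reference
conditions (200 fps, 0.005% relative noise, 15 um field of view): recovery
of a hydrodynamic radius by the covariance estimator plus hindrance
inversion, and recovery of a population-mean molecular weight (and its
FWHM resolution) by the full render -> preprocess -> track -> estimate
pipeline.  Used by the validation suite and the results-reproduction
script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import ChannelConfig, PlanConfig, RunConfig, SpeciesConfig
from .geometry import get_channel
from .hydro import HydroContext, stokes_radius_from_diffusivity
from .infer import fit_population, population_histogram
from .pipeline import run_pipeline
from .simulate import SimulationPlan, SpeciesSpec, simulate_trajectory

__all__ = ["radius_recovery_cve", "mw_recovery_pipeline", "resolution_scenario"]


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def radius_recovery_cve(
    seed: int,
    rs_nm: float = 8.6,
    channel: str = "I",
    n_trajectories: int = 100,
    n_steps: int = 1000,
    dt: float = 0.005,
    loc_noise_nm: float = 30.0,
) -> float:
    """Mean hydrodynamic radius recovered from simulated trajectories.

    Trajectories are simulated at the hindered diffusivity of a sphere of
    ``rs_nm`` in the named channel (unconfined walk: the simulation domain
    is made much larger than the excursions so the reflecting ends are
    never felt), Gaussian localization noise is added, the covariance
    estimator gives D per trajectory, and the hindered Stokes--Einstein
    relation is inverted per trajectory.  Returns the mean radius (nm).
    """
    from .infer import cve_diffusivity

    ch = get_channel(channel)
    ctx = dataclasses.replace(
        HydroContext(), equivalent_radius_nm=ch.equivalent_radius_nm
    )
    sp = SpeciesSpec("probe", 0.0, rs_nm=rs_nm)
    plan = SimulationPlan(
        channel=ch,
        dt=dt,
        n_frames=n_steps,
        substeps_per_frame=1,
        domain_length_nm=4.0e5,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed)
    radii = []
    for _ in range(n_trajectories):
        pos = simulate_trajectory(sp, plan, ctx, rng, x0=ch.fov_length_nm / 2)
        x = pos[:, 0] + loc_noise_nm * rng.standard_normal(n_steps)
        D = cve_diffusivity(x, dt)
        radii.append(stokes_radius_from_diffusivity(D, ctx))
    return float(np.mean(radii))


def _single_species_config(
    name: str, mw_kda: float, rs_nm: float, channel: str,
    n_frames: int, n_scenes: int, seed: int,
) -> RunConfig:
    return RunConfig(
        channel=ChannelConfig(name=channel),
        species=[SpeciesConfig(name=name, mw_kda=mw_kda, rs_nm=rs_nm)],
        plan=PlanConfig(n_frames=n_frames, n_scenes=n_scenes),
        seed=seed,
    )


def mw_recovery_pipeline(
    seed: int,
    name: str,
    mw_kda: float,
    rs_nm: float,
    channel: str,
    n_scenes: int = 200,
    n_frames: int = 500,
) -> tuple[float, float, int]:
    """Full-pipeline population-mean MW recovery for one species.

    ``n_scenes`` independent single-molecule scenes of ``n_frames`` frames
    are simulated, passed through raw-intensity emulation, preprocessing,
    tracking and per-trajectory estimation; one Gaussian is fitted to the
    N-weighted MW histogram.  Returns (center kDa, FWHM kDa, number of
    trajectories).
    """
    cfg = _single_species_config(
        name, mw_kda, rs_nm, channel, n_frames, n_scenes, seed
    )
    res = run_pipeline(cfg)
    pop = res.population
    if pop is None:
        raise RuntimeError("no population recovered")
    return pop.mean, pop.resolution, len(res.estimates)


def resolution_scenario(
    seed: int,
    name: str = "thyroglobulin",
    mw_kda: float = 669.0,
    rs_nm: float = 8.6,
    channel: str = "I",
    n_trajectories: int = 300,
    length_range: tuple[int, int] = (500, 1100),
) -> tuple[float, float, int]:
    """MW resolution (FWHM) with trajectory lengths drawn uniformly.

    One molecule per scene; scene i runs for a number of frames drawn
    uniformly from ``length_range``.  All recovered trajectories are
    pooled into one N-weighted MW histogram fitted with one Gaussian.
    Returns (center kDa, FWHM kDa, number of trajectories).
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(_child_seed(root))
    children = root.spawn(n_trajectories)
    frames = []
    for child in children:
        n_frames = int(rng.integers(length_range[0], length_range[1] + 1))
        cfg = _single_species_config(
            name, mw_kda, rs_nm, channel, n_frames, 1, _child_seed(child)
        )
        res = run_pipeline(cfg)
        if len(res.estimates):
            frames.append(res.estimates.drop(columns=["weight"]))
    pooled = pd.concat(frames, ignore_index=True)
    pop = fit_population(population_histogram(pooled, field="mw_kda"))
    return pop.mean, pop.resolution, len(pooled)
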