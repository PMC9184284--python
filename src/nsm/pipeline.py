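"""End-to-end pipeline: simulate (or ingest) -> preprocess -> track -> infer.

``run_pipeline`` executes a :class:`~nsm.config.RunConfig` scenario: for
each of ``n_scenes`` independent scenes it simulates the species in the
channel, emulates a raw intensity movie, preprocesses it back to contrast,
detects/links/filters trajectories, and finally pools all trajectories
into per-molecule estimates and a Gaussian population fit.  All artifacts
carry the config hash and seed; stage counts are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import ChannelGeometry
from .hydro import HydroContext, hindered_diffusivity
from .infer import (
    PopulationResult,
    characterize,
    estimates_frame,
    fit_population,
    population_histogram,
)
from .kymograph import Kymograph
from .preprocess import preprocess
from .simulate import (
    GroundTruth,
    SpeciesSpec,
    raw_from_contrast,
    simulate_experiment,
)
from .track import (
    Trajectory,
    blur_template_sigma,
    default_gate_nm,
    detect_kymograph,
    filter_trajectories,
    link,
    trajectories_frame,
)

logger = logging.getLogger("nsm")

__all__ = ["PipelineResult", "run_pipeline", "analyze_kymograph", "scatter_report"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produced."""

    config: RunConfig
    kymographs: list[Kymograph]
    truths: list[GroundTruth]
    trajectories: list[Trajectory]
    estimates: pd.DataFrame
    population: PopulationResult | None
    report: dict


def _species_models(config: RunConfig) -> list[SpeciesSpec]:
    return [s.to_model() for s in config.species]


def _auto_gate(
    config: RunConfig,
    species: list[SpeciesSpec],
    channel: ChannelGeometry,
    ctx: HydroContext,
    dt: float,
) -> tuple[float, float]:
    """(linking gate nm, fastest species D in um^2/s) for this scenario."""
    ctx_eff = dataclasses.replace(ctx, equivalent_radius_nm=channel.equivalent_radius_nm)
    d_max = config.track.d_max_um2_s
    drift = 0.0
    if species:
        d_max = max(
            hindered_diffusivity(sp.radius_nm, ctx_eff) * 1e12 for sp in species
        )
        drift = max(abs(sp.drift_velocity) for sp in species)
    gate = (
        config.track.gate_nm
        if config.track.gate_nm is not None
        else default_gate_nm(dt, d_max, drift)
    )
    return gate, d_max


def analyze_kymograph(
    kymo: Kymograph,
    config: RunConfig,
    gate_nm: float,
    flow: bool,
    d_max_um2_s: float | None = None,
) -> list[Trajectory]:
    """Contrast kymograph -> filtered trajectories (detection + linking)."""
    optics = config.optics.to_model()
    template = config.track.template_sigma_nm
    if template is None and d_max_um2_s is not None:
        template = blur_template_sigma(optics.psf_sigma, d_max_um2_s, kymo.dt)
    dets = detect_kymograph(
        kymo,
        optics,
        threshold_kappa=config.track.kappa,
        ioc_halfwidth_nm=config.track.ioc_halfwidth_nm,
        template_sigma_nm=template,
    )
    band = dets.attrs.get("detection_band")
    trajs = link(
        dets, kymo.dt, gate_nm, gap_frames=config.track.gap_frames, flow=flow
    )
    if band is not None:
        for tr in trajs:
            tr.flags["detection_band"] = band
    kept = filter_trajectories(
        trajs,
        min_N=config.track.min_n,
        immobile_window=config.track.immobile_window,
        immobile_sigma_factor=config.track.immobile_sigma_factor,
    )
    logger.info(
        "scene: %d detections -> %d raw trajectories -> %d kept",
        len(dets), len(trajs), len(kept),
    )
    return kept


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    preprocess_stage: bool = True,
    keep_kymographs: bool = False,
) -> PipelineResult:
    """Run the configured scenario end to end (deterministic given seed)."""
    channel = config.channel.to_model()
    optics = config.optics.to_model()
    ctx = config.hydro.to_model()
    species = _species_models(config)
    dt = optics.dt
    flow = config.track.flow
    if flow is None:
        flow = any(sp.drift_velocity != 0 for sp in species)
    gate, d_max = _auto_gate(config, species, channel, ctx, dt)

    seeds = np.random.SeedSequence(config.seed).spawn(config.plan.n_scenes)
    kymographs: list[Kymograph] = []
    truths: list[GroundTruth] = []
    all_trajs: list[Trajectory] = []
    for i, ss in enumerate(seeds):
        scene_seed = int(ss.generate_state(1)[0] % (2**31))
        plan = config.plan.to_model(channel, dt, scene_seed)
        kymo, truth = simulate_experiment(species, plan, optics, ctx)
        if preprocess_stage:
            rng = np.random.default_rng(scene_seed + 1)
            raw = raw_from_contrast(kymo, gain_drift=2e-5, rng=rng)
            kymo = preprocess(raw)
        trajs = analyze_kymograph(kymo, config, gate, flow, d_max)
        for tr in trajs:
            tr.id = len(all_trajs)
            all_trajs.append(tr)
        truths.append(truth)
        if keep_kymographs or i == 0:
            kymographs.append(kymo)

    estimates = [
        characterize(tr, channel, optics, ctx, flow=flow) for tr in all_trajs
    ]
    est_df = estimates_frame(estimates)

    population = None
    if len(est_df) and est_df[config.infer.field].notna().any():
        hist = population_histogram(
            est_df, field=config.infer.field, bin_width=config.infer.bin_width
        )
        population = fit_population(hist, n_components=config.infer.n_components)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_scenes": config.plan.n_scenes,
        "n_trajectories": len(all_trajs),
        "n_estimates": len(est_df),
        "field": config.infer.field,
        "population": population.summary() if population is not None else None,
    }

    result = PipelineResult(
        config, kymographs, truths, all_trajs, est_df, population, report
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.kymographs:
        k = result.kymographs[0]
        k.metadata["config_hash"] = result.report["config_hash"]
        k.save(outdir / "kymo.tiff")
    if result.truths:
        pd.concat(
            [t.to_frame().assign(scene=i) for i, t in enumerate(result.truths)],
            ignore_index=True,
        ).to_csv(outdir / "truth.csv", index=False)
    trajectories_frame(result.trajectories).to_csv(outdir / "traj.csv", index=False)
    result.estimates.to_csv(outdir / "est.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2))


def scatter_report(
    estimates: pd.DataFrame,
    populations: dict[str, PopulationResult] | None = None,
    globular_b: float = 0.88,
    path: str | Path | None = None,
):
    """MW–R_s scatter of per-trajectory estimates, colored by N.

    Overlays the globular scaling line R_s = b MW^(1/3) and, when
    population fits for "mw_kda"/"rs_nm" are supplied, an ellipse per
    population centered on the fitted means with diameters equal to the
    FWHM resolutions.  Returns the matplotlib figure and a summary dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    df = estimates.dropna(subset=["mw_kda", "rs_nm"])
    if len(df) == 0:
        raise ValueError("no valid (MW, R_s) estimates to plot")

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(df["mw_kda"], df["rs_nm"], c=df["N"], s=12, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="trajectory length N")

    mw_line = np.linspace(max(df["mw_kda"].min() * 0.5, 1.0), df["mw_kda"].max() * 1.5, 200)
    ax.plot(mw_line, globular_b * mw_line ** (1 / 3), "gray", lw=1, label="globular")

    summary: dict = {"n_points": int(len(df))}
    if populations:
        mw_pop = populations.get("mw_kda")
        rs_pop = populations.get("rs_nm")
        if mw_pop is not None and rs_pop is not None:
            for cm, cr in zip(mw_pop.components, rs_pop.components):
                ax.add_patch(
                    Ellipse(
                        (cm.center, cr.center), cm.fwhm, cr.fwhm,
                        fill=False, color="crimson", lw=1.5,
                    )
                )
            summary["ellipses"] = [
                {
                    "mw_center": cm.center, "mw_fwhm": cm.fwhm,
                    "rs_center": cr.center, "rs_fwhm": cr.fwhm,
                }
                for cm, cr in zip(mw_pop.components, rs_pop.components)
            ]
    ax.set_xlabel("MW (kDa)")
    ax.set_ylabel(r"$R_s$ (nm)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig, summary
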