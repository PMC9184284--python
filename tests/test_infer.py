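import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsm.hydro import hindered_diffusivity
from nsm.infer import (
    FWHM_FACTOR,
    TrajectoryEstimate,
    characterize,
    cve_diffusivity,
    estimates_frame,
    fit_population,
    population_histogram,
    trajectory_ioc,
)
from nsm.track import Trajectory


def _traj(x, ioc=-0.5, dt=0.005, frames=None, flags=None):
    x = np.asarray(x, float)
    frames = np.arange(len(x)) if frames is None else np.asarray(frames)
    return Trajectory(
        0, frames, x, np.full(len(x), float(ioc)), np.full(len(x), 5.0), dt,
        flags or {},
    )


class TestTrajectoryIOC:
    def test_constant(self):
        assert trajectory_ioc(_traj(np.zeros(5), ioc=-0.5)) == -0.5

    def test_mean(self):
        tr = _traj(np.zeros(3))
        tr.ioc_n = np.array([-1.0, -2.0, -3.0])
        assert trajectory_ioc(tr) == -2.0


class TestCVE:
    def test_constant_displacement(self):
        # dx = 1 nm each step at dt = 5 ms: 1/(2 dt) + 1/dt = 300 nm^2/s
        x = np.arange(5.0)
        assert cve_diffusivity(x, 0.005) * 1e18 == pytest.approx(300.0)

    def test_alternating_noise_signature_is_negative(self):
        delta = 3.0
        x = np.array([0, delta, 0, delta, 0], float)
        # dx = [d,-d,d,-d]: mean dx^2 = d^2, mean dx_n dx_{n+1} = -d^2
        expected = delta**2 / (2 * 0.005) - delta**2 / 0.005
        assert cve_diffusivity(x, 0.005) * 1e18 == pytest.approx(expected)
        assert expected == pytest.approx(-(delta**2) / (2 * 0.005))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cve_diffusivity(np.array([0.0, 1.0]), 0.005)

    def test_unbiased_under_localization_noise(self):
        # covariance term cancels the static-noise bias by construction
        D = 10.0e6  # nm^2/s
        dt, n, reps = 0.005, 10_000, 100
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(reps):
            x = np.cumsum(rng.normal(0, math.sqrt(2 * D * dt), n))
            x = x + rng.normal(0, 30.0, n)
            ests.append(cve_diffusivity(x, dt) * 1e18)
        assert np.mean(ests) == pytest.approx(D, rel=0.02)

    def test_variance_shrinks_with_length(self):
        D, dt = 10.0e6, 0.005
        rng = np.random.default_rng(7)

        def spread(n):
            vals = [
                cve_diffusivity(
                    np.cumsum(rng.normal(0, math.sqrt(2 * D * dt), n)), dt
                )
                for _ in range(150)
            ]
            return np.var(vals)

        assert spread(4000) < spread(1000) / 2

    def test_drift_subtraction(self):
        rng = np.random.default_rng(3)
        D, dt, v = 5.0e6, 0.005, 2.0e6  # strong drift, 2 um/s
        x = np.cumsum(v * dt + rng.normal(0, math.sqrt(2 * D * dt), 5000))
        d_flow = cve_diffusivity(x, dt, subtract_drift=True) * 1e18
        assert d_flow == pytest.approx(D, rel=0.15)

    def test_gap_frames_skipped(self):
        # a 10-frame hole must not create a giant displacement
        rng = np.random.default_rng(5)
        D, dt = 10.0e6, 0.005
        x = np.cumsum(rng.normal(0, math.sqrt(2 * D * dt), 2000))
        frames = np.arange(2000)
        keep = (frames < 900) | (frames >= 1100)
        d = cve_diffusivity(x[keep], dt, frames=frames[keep]) * 1e18
        assert d == pytest.approx(D, rel=0.25)


class TestCharacterize:
    def test_nonpositive_D_flagged_not_dropped(self, channel_I):
        x = np.tile([0.0, 3.0], 50)[:100]  # pure alternating noise
        est = characterize(_traj(x), channel_I)
        assert "nonpositive_D" in est.flags
        assert math.isnan(est.rs_nm)
        assert est.mw_kda > 0  # mass still reported

    def test_recovers_simulated_thyroglobulin(self, channel_I, ctx_I):
        D = hindered_diffusivity(8.6, ctx_I)
        rng = np.random.default_rng(21)
        dt = 0.005
        x = np.cumsum(rng.normal(0, math.sqrt(2 * D * 1e18 * dt), 2000))
        tr = _traj(x, ioc=-1.1687357381368149)
        est = characterize(tr, channel_I)
        assert est.mw_kda == pytest.approx(669.0, rel=1e-6)
        assert est.rs_nm == pytest.approx(8.6, rel=0.15)


class TestPopulationHistogram:
    def test_single_trajectory_single_bin(self):
        ests = [TrajectoryEstimate(0, 100, -0.5, 1e-11, 66.0, 3.5)]
        edges, counts = population_histogram(ests)
        assert counts.sum() == pytest.approx(1.0)
        assert (counts > 0).sum() == 1

    def test_weights_proportional_to_length(self):
        ests = [
            TrajectoryEstimate(0, 100, -0.5, 1e-11, 60.0, 3.5),
            TrajectoryEstimate(1, 300, -0.6, 1e-11, 80.0, 3.6),
        ]
        edges, counts = population_histogram(ests, bin_width=5.0)
        nz = counts[counts > 0]
        assert sorted(nz) == pytest.approx([0.25, 0.75])

    def test_no_valid_estimates(self):
        ests = [TrajectoryEstimate(0, 100, -0.5, 1e-11, math.nan, math.nan)]
        with pytest.raises(ValueError):
            population_histogram(ests)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=2, max_value=40))
    def test_mass_conservation(self, n):
        rng = np.random.default_rng(n)
        ests = [
            TrajectoryEstimate(i, int(rng.integers(50, 1000)), -0.5, 1e-11,
                               float(rng.normal(66, 5)), 3.5)
            for i in range(n)
        ]
        _, counts = population_histogram(ests)
        assert counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimer_fraction_recovered(self):
        rng = np.random.default_rng(9)
        ests = []
        for i in range(2000):
            dimer = rng.random() < 0.05
            mw = rng.normal(132.0 if dimer else 66.0, 3.0)
            ests.append(TrajectoryEstimate(i, 200, -0.5, 1e-11, mw, 3.5))
        edges, counts = population_histogram(ests, bin_width=5.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dimer_mass = counts[centers > 100].sum()
        assert dimer_mass == pytest.approx(0.05, abs=0.015)


class TestFitPopulation:
    def test_gaussian_sample_center_and_fwhm(self):
        rng = np.random.default_rng(4)
        ests = [
            TrajectoryEstimate(i, 1, -0.5, 1e-11, float(v), 3.5)
            for i, v in enumerate(rng.normal(66.0, 5.0, 10_000))
        ]
        pop = fit_population(population_histogram(ests))
        assert pop.mean == pytest.approx(66.0, abs=0.5)
        assert pop.resolution == pytest.approx(FWHM_FACTOR * 5.0, abs=1.0)
        assert pop.components[0].fwhm == FWHM_FACTOR * pop.components[0].sigma

    def test_single_bin_fwhm_floor(self):
        ests = [
            TrajectoryEstimate(i, 100, -0.5, 1e-11, 66.0, 3.5) for i in range(20)
        ]
        pop = fit_population(population_histogram(ests, bin_width=2.0))
        assert pop.moment_fallback
        assert pop.resolution <= 2.0 + 1e-9

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            fit_population((np.array([0.0, 1.0]), np.array([0.0])))

    def test_multicomponent_requires_init(self):
        rng = np.random.default_rng(5)
        ests = [
            TrajectoryEstimate(i, 1, -0.5, 1e-11, float(v), 3.5)
            for i, v in enumerate(rng.normal(66.0, 5.0, 500))
        ]
        hist = population_histogram(ests)
        with pytest.raises(ValueError, match="initialization"):
            fit_population(hist, n_components=2)

    def test_two_component_fit(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate(
            [rng.normal(66, 4, 8000), rng.normal(132, 5, 2000)]
        )
        ests = [
            TrajectoryEstimate(i, 1, -0.5, 1e-11, float(v), 3.5)
            for i, v in enumerate(vals)
        ]
        hist = population_histogram(ests)
        pop = fit_population(
            hist, n_components=2, init=[(0.8, 66, 4), (0.2, 132, 5)]
        )
        centers = sorted(c.center for c in pop.components)
        assert centers[0] == pytest.approx(66, abs=2)
        assert centers[1] == pytest.approx(132, abs=3)


def test_estimates_frame_weights_sum_to_one():
    ests = [
        TrajectoryEstimate(i, n, -0.5, 1e-11, 66.0, 3.5)
        for i, n in enumerate([100, 200, 700])
    ]
    df = estimates_frame(ests)
    assert df["weight"].sum() == pytest.approx(1.0)
    assert df["weight"].iloc[2] == pytest.approx(0.7)
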