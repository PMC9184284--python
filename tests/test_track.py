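import math

import numpy as np
import pandas as pd
import pytest

from nsm.kymograph import Kymograph
from nsm.optics import OpticalModel
from nsm.simulate import (
    SimulationPlan,
    SpeciesSpec,
    simulate_experiment,
    simulate_trajectory,
)
from nsm.track import (
    Trajectory,
    blur_template_sigma,
    default_gate_nm,
    detect_frame,
    detect_kymograph,
    filter_trajectories,
    link,
)

SIGMA = 100.0
PITCH = 30.0
N_PIX = 501


def _dip_line(x0, ioc, noise=5e-5, rng=None, n_pix=N_PIX):
    """Static unblurred Gaussian dip of integral ``ioc`` (negative, nm)."""
    x = PITCH * np.arange(n_pix)
    line = ioc * np.exp(-0.5 * ((x - x0) / SIGMA) ** 2) / (SIGMA * math.sqrt(2 * math.pi))
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        line = line + rng.normal(0, noise, n_pix)
    return line


def _kymo(lines):
    return Kymograph(np.asarray(lines, float), 0.005, PITCH)


class TestDetection:
    def test_pure_noise_false_positive_rate(self):
        # expected false-positive rate per line << 1e-2 at kappa = 5
        rng = np.random.default_rng(42)
        lines = rng.normal(0, 5e-5, (500, N_PIX))
        dets = detect_kymograph(_kymo(lines), OpticalModel())
        assert len(dets) <= 2

    def test_single_dip_localization_and_ioc(self):
        # SNR 10 dip: peak amplitude = 10 x noise level
        ioc = -10 * 5e-5 * SIGMA * math.sqrt(2 * math.pi)
        rng = np.random.default_rng(1)
        x_true = 7432.1
        lines = [_dip_line(x_true, ioc, rng=rng) for _ in range(25)]
        dets = detect_kymograph(
            _kymo(lines), OpticalModel(), ioc_halfwidth_nm=300.0
        )
        assert len(dets) == 25
        assert np.abs(dets.x_nm - x_true).mean() < 15.0
        assert abs(dets.ioc_nm.mean() / ioc - 1) < 0.05
        # fit-based and windowed-sum contrasts agree for unblurred dips
        assert np.abs(dets.ioc_fit_nm / dets.ioc_nm - 1).mean() < 0.1

    def test_two_separated_dips_both_found(self):
        line = _dip_line(5000.0, -0.5, noise=0) + _dip_line(5500.0, -0.5, noise=0)
        rng = np.random.default_rng(2)
        line = line + rng.normal(0, 5e-5, N_PIX)
        dets = detect_frame(line, OpticalModel(), ioc_halfwidth_nm=300.0)
        assert len(dets) == 2
        xs = sorted(d.x for d in dets)
        assert xs[0] == pytest.approx(5000, abs=30)
        assert xs[1] == pytest.approx(5500, abs=30)

    def test_edge_candidates_rejected(self):
        line = _dip_line(100.0, -1.0, noise=0)
        dets = detect_frame(line, OpticalModel())
        assert dets == []

    def test_localization_error_decreases_with_snr(self):
        errs = []
        for snr in (5.0, 20.0, 80.0):
            ioc = -snr * 5e-5 * SIGMA * math.sqrt(2 * math.pi)
            rng = np.random.default_rng(3)
            lines = [_dip_line(8000.0, ioc, rng=rng) for _ in range(60)]
            dets = detect_kymograph(
                _kymo(lines), OpticalModel(), ioc_halfwidth_nm=300.0
            )
            errs.append(np.abs(dets.x_nm - 8000.0).mean())
        assert errs[0] > errs[1] > errs[2]
        # reported uncertainty tracks the empirical error scale
        assert errs[2] < 10.0

    def test_blur_template_sigma(self):
        assert blur_template_sigma(100.0, 0.0, 0.005) == 100.0
        assert blur_template_sigma(100.0, 43.7, 0.005) == pytest.approx(
            math.sqrt(100**2 + 43.7e6 * 0.005 / 3)
        )


def _det_df(rows):
    return pd.DataFrame(
        rows, columns=["frame", "x_nm", "ioc_nm", "loc_sigma_nm"]
    ).assign(snr=10.0)


class TestLinking:
    def test_single_molecule_single_trajectory(self):
        rng = np.random.default_rng(0)
        x = 5000 + np.cumsum(rng.normal(0, 100, 200))
        df = _det_df([(i, x[i], -0.5, 5.0) for i in range(200)])
        trajs = link(df, 0.005, gate_nm=1000.0)
        assert len(trajs) == 1
        assert trajs[0].N == 200

    def test_two_well_separated_molecules_no_switches(self):
        rng = np.random.default_rng(1)
        xa = 3000 + np.cumsum(rng.normal(0, 80, 300))
        xb = 11000 + np.cumsum(rng.normal(0, 80, 300))
        rows = [(i, xa[i], -0.5, 5.0) for i in range(300)]
        rows += [(i, xb[i], -0.7, 5.0) for i in range(300)]
        trajs = link(_det_df(rows), 0.005, gate_nm=1000.0)
        assert len(trajs) == 2
        for tr in trajs:
            # each trajectory stays on one side: zero identity switches
            assert (tr.x < 7000).all() or (tr.x > 7000).all()
            assert tr.N == 300

    def test_gap_longer_than_tolerance_splits(self):
        rows = [(i, 5000.0, -0.5, 5.0) for i in range(50)]
        rows += [(i, 5000.0, -0.5, 5.0) for i in range(56, 100)]  # 6-frame gap
        trajs = link(_det_df(rows), 0.005, gate_nm=500.0, gap_frames=3)
        assert sorted(tr.N for tr in trajs) == [44, 50]

    def test_short_gap_bridged(self):
        rows = [(i, 5000.0, -0.5, 5.0) for i in range(50)]
        rows += [(i, 5000.0, -0.5, 5.0) for i in range(52, 100)]  # 2-frame gap
        trajs = link(_det_df(rows), 0.005, gate_nm=500.0, gap_frames=3)
        assert len(trajs) == 1 and trajs[0].N == 98

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        xa = 3000 + np.cumsum(rng.normal(0, 80, 100))
        xb = 9000 + np.cumsum(rng.normal(0, 80, 100))
        rows = [(i, xa[i], -0.5, 5.0) for i in range(100)]
        rows += [(i, xb[i], -0.7, 5.0) for i in range(100)]
        df = _det_df(rows)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        t1 = link(df, 0.005, gate_nm=800.0)
        t2 = link(shuffled, 0.005, gate_nm=800.0)
        key = lambda trs: sorted(tuple(np.round(tr.x, 9)) for tr in trs)
        assert key(t1) == key(t2)

    def test_flow_recentering_links_drifting_particle(self):
        # 2.5 um/frame drift, far beyond the gate without recentering
        rows = [(i, 1000.0 + 2500.0 * i, -0.5, 5.0) for i in range(5)]
        trajs = link(_det_df(rows), 0.005, gate_nm=1000.0, flow=True)
        assert len(trajs) == 1 and trajs[0].N == 5

    def test_default_gate(self):
        assert default_gate_nm(0.005, 30.0) == pytest.approx(
            4 * math.sqrt(2 * 30e6 * 0.005)
        )
        assert default_gate_nm(0.005, 30.0, drift_nm_s=2000.0) == pytest.approx(
            4 * math.sqrt(2 * 30e6 * 0.005) + 10.0
        )


def _traj(x, loc_sigma=5.0, frames=None):
    x = np.asarray(x, float)
    frames = np.arange(len(x)) if frames is None else frames
    return Trajectory(
        0, frames, x, np.full(len(x), -0.5), np.full(len(x), loc_sigma), 0.005
    )


class TestFilter:
    def test_short_trajectory_dropped(self):
        rng = np.random.default_rng(0)
        trajs = [_traj(np.cumsum(rng.normal(0, 100, 10)))]
        assert filter_trajectories(trajs, min_N=50) == []

    def test_free_trajectory_kept_intact(self):
        rng = np.random.default_rng(1)
        trajs = [_traj(5000 + np.cumsum(rng.normal(0, 100, 300)))]
        kept = filter_trajectories(trajs, min_N=50)
        assert len(kept) == 1 and kept[0].N == 300

    def test_bound_segment_excised_and_segments_reemitted(self):
        rng = np.random.default_rng(2)
        free1 = 5000 + np.cumsum(rng.normal(0, 100, 150))
        bound = free1[-1] + rng.normal(0, 2.0, 200)  # jitter ~ loc noise
        free2 = bound[-1] + np.cumsum(rng.normal(0, 100, 150))
        x = np.concatenate([free1, bound, free2])
        kept = filter_trajectories([_traj(x, loc_sigma=5.0)], min_N=50)
        assert len(kept) == 2
        assert all(tr.flags.get("bound_segment_excised") for tr in kept)
        assert all(tr.N >= 100 for tr in kept)

    def test_immobile_whole_trajectory_removed(self):
        rng = np.random.default_rng(3)
        x = 5000 + rng.normal(0, 2.0, 200)
        assert filter_trajectories([_traj(x, loc_sigma=5.0)], min_N=50) == []


class TestOnSimulatedScenes:
    def test_recall_two_molecules(self, channel_I):
        optics = OpticalModel()
        plan = SimulationPlan(
            channel=channel_I, n_frames=400, rng_seed=17,
            domain_length_nm=channel_I.fov_length_nm,
        )
        a = SpeciesSpec("thyro", 669.0, rs_nm=8.6)
        kymo, truth = simulate_experiment([a, a], plan, optics)
        tmpl = blur_template_sigma(100.0, 11.0, 0.005)
        dets = detect_kymograph(kymo, optics, template_sigma_nm=tmpl)
        band = dets.attrs["detection_band"]
        # recall over frames where the molecules are inside the detection
        # band and mutually resolvable
        fx = np.stack([m.frame_positions for m in truth.molecules])
        in_band = (fx > band[0]) & (fx < band[1])
        resolvable = np.abs(fx[0] - fx[1]) > 4 * tmpl
        expected = (in_band & resolvable[None, :]).sum()
        per_frame = dets.groupby("frame").size()
        found = sum(
            min(per_frame.get(f, 0), int(in_band[:, f].sum()))
            for f in range(plan.n_frames)
            if resolvable[f]
        )
        assert found / max(expected, 1) >= 0.95

    def test_separated_molecules_tracked_without_switches(self, channel_I, ctx_I):
        # two slow molecules kept > 2 gates apart: two pure trajectories
        from nsm.simulate import GroundTruth, MoleculeTruth, render_kymograph

        optics = OpticalModel()
        plan = SimulationPlan(
            channel=channel_I, n_frames=250, rng_seed=8,
            domain_length_nm=channel_I.fov_length_nm,
        )
        sp = SpeciesSpec("slow", 669.0, rs_nm=8.6, d_um2_s=3.0)
        rng = np.random.default_rng(5)
        mols = []
        for mid, x0 in ((0, 4000.0), (1, 11000.0)):
            pos = simulate_trajectory(sp, plan, ctx_I, rng, x0=x0)
            mols.append(MoleculeTruth(
                mid, "slow", 669.0, 8.6, 3.0e-12, -1.1687, pos,
                np.zeros(plan.n_frames, bool),
            ))
        truth = GroundTruth(mols, plan)
        fx = np.stack([m.frame_positions for m in mols])
        gate = default_gate_nm(0.005, 3.0)
        assert np.abs(fx[0] - fx[1]).min() > 2 * gate  # premise holds

        kymo = render_kymograph(truth, optics, plan, np.random.default_rng(6))
        tmpl = blur_template_sigma(100.0, 3.0, 0.005)
        dets = detect_kymograph(kymo, optics, template_sigma_nm=tmpl)
        kept = filter_trajectories(link(dets, 0.005, gate), min_N=50)
        assert len(kept) == 2
        for tr in kept:
            d = np.abs(fx[:, tr.frames] - tr.x[None, :])
            owner = d.argmin(axis=0)
            assert (owner == owner[0]).all()  # zero identity switches
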