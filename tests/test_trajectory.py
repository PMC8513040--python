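"""ZUPT detection, orientation windows, the error-state filter and spatial features."""

import numpy as np
import pytest

from stairgait import events as ev
from stairgait import synthetic as syn
from stairgait import trajectory as tj
from stairgait.types import GaitEventSet, ImuSequence, StrideEvents

from conftest import align_foot, truth_border_set

FS = 204.8


def _static_seq(n: int) -> ImuSequence:
    return ImuSequence(acc=np.tile([0, 0, 1.0], (n, 1)), gyr=np.zeros((n, 3)), sampling_rate=FS)


def _zupt_oracle(seq: ImuSequence, w: int, acc_thr: float, gyr_thr: float):
    """Brute-force per-window evaluation of both detectors."""
    n = len(seq)
    acc_mask = np.zeros(n, dtype=bool)
    gyr_mask = np.zeros(n, dtype=bool)
    dev = np.abs(np.linalg.norm(seq.acc, axis=1) - 1.0)
    sq = (seq.gyr**2).sum(axis=1)
    for s in range(n - w + 1):
        if dev[s : s + w].max() < acc_thr:
            acc_mask[s : s + w] = True
        if np.sqrt(sq[s : s + w].mean()) < gyr_thr:
            gyr_mask[s : s + w] = True
    return acc_mask, gyr_mask


class TestZupt:
    def test_perfectly_static_input_is_all_true(self):
        seq = _static_seq(500)
        z = tj.detect_zupt(seq)
        assert z.combined.all()

    def test_fast_rotation_leaves_only_ms_windows(self):
        n = 1000
        gyr = np.full((n, 3), 100.0 / np.sqrt(3))
        acc = np.tile([0, 0, 1.5], (n, 1))  # 0.5 g deviation
        seq = ImuSequence(acc=acc, gyr=gyr, sampling_rate=FS)
        es = GaitEventSet(events=[StrideEvents(tc=1, ic=2, ms=500, valid=True)], sampling_rate=FS)
        z = tj.detect_zupt(seq, es)
        assert not z.acc.any() and not z.gyr.any()
        half = int(round(0.025 * FS))
        expected = np.zeros(n, dtype=bool)
        expected[500 - half : 500 + half + 1] = True
        assert np.array_equal(z.combined, expected)

    def test_matches_brute_force_on_random_signal(self):
        rng = np.random.default_rng(8)
        n = 5000
        acc = np.tile([0, 0, 1.0], (n, 1)) + rng.normal(0, 0.08, (n, 3))
        gyr = rng.normal(0, 8, (n, 3))
        seq = ImuSequence(acc=acc, gyr=gyr, sampling_rate=FS)
        z = tj.detect_zupt(seq)
        w = int(round(0.15 * FS))
        acc_o, gyr_o = _zupt_oracle(seq, w, 0.1, 10.0)
        assert np.array_equal(z.acc, acc_o)
        assert np.array_equal(z.gyr, gyr_o)

    def test_combined_is_or_of_components(self):
        rng = np.random.default_rng(9)
        seq = ImuSequence(
            acc=np.tile([0, 0, 1.0], (2000, 1)) + rng.normal(0, 0.1, (2000, 3)),
            gyr=rng.normal(0, 12, (2000, 3)),
            sampling_rate=FS,
        )
        es = GaitEventSet(events=[StrideEvents(tc=1, ic=2, ms=700)], sampling_rate=FS)
        z = tj.detect_zupt(seq, es)
        assert np.array_equal(z.combined, z.acc | z.gyr | z.ms_event)


class TestOrientationWindows:
    def test_long_static_record_is_one_window_plus_forced_endpoints(self):
        seq = _static_seq(int(10 * FS))
        ws = tj.find_orientation_windows(seq)
        natural = [w for w in ws if not w.forced]
        assert len(natural) == 1
        assert natural[0].start == 0 and natural[0].end == len(seq)
        assert sum(w.forced for w in ws) == 2

    def test_single_quiet_mid_segment_found(self):
        rng = np.random.default_rng(10)
        n = int(6 * FS)
        acc = np.tile([0, 0, 1.0], (n, 1)) + rng.normal(0, 0.5, (n, 3))
        a, b = 600, 600 + int(0.4 * FS)
        acc[a:b] = [0, 0, 1.0]
        seq = ImuSequence(acc=acc, gyr=np.zeros((n, 3)), sampling_rate=FS)
        with pytest.warns(UserWarning):
            ws = tj.find_orientation_windows(seq)
        natural = [w for w in ws if not w.forced]
        assert len(natural) == 1
        w = int(round(0.3 * FS))
        # oracle: merged run of all passing window starts
        ok = [
            s
            for s in range(n - w + 1)
            if (acc[s : s + w].var(axis=0) < 0.015).all()
        ]
        assert natural[0].start == ok[0] and natural[0].end == ok[-1] + w

    def test_no_quiet_segment_yields_only_forced_updates(self):
        rng = np.random.default_rng(11)
        n = int(2 * FS)
        acc = rng.normal(0, 0.5, (n, 3))
        seq = ImuSequence(acc=acc, gyr=np.zeros((n, 3)), sampling_rate=FS)
        with pytest.warns(UserWarning):
            ws = tj.find_orientation_windows(seq)
        assert len(ws) == 2 and all(w.forced for w in ws)


class TestReconstruction:
    def test_static_record_stays_below_one_millimetre(self):
        seq = _static_seq(int(10 * FS))
        z = tj.detect_zupt(seq)
        traj = tj.reconstruct_trajectory(seq, z, tj.find_orientation_windows(seq))
        assert np.linalg.norm(traj.position - traj.position[0], axis=1).max() < 1e-3

    def test_level_walking_height_change_below_two_centimetres(self, level_walk_nf):
        body, tr = align_foot(level_walk_nf, "left")
        es = ev.detect_events(body, truth_border_set(tr))
        z = tj.detect_zupt(body, es)
        traj = tj.reconstruct_trajectory(body, z, tj.find_orientation_windows(body))
        sp = tj.compute_spatial_params(traj, es)
        assert np.abs(sp.height).max() < 0.02

    def test_double_step_ascent_recovers_staircase_height(self, ascending_walk_nf):
        body, tr = align_foot(ascending_walk_nf, "left")
        es = ev.detect_events(body, truth_border_set(tr))
        z = tj.detect_zupt(body, es)
        traj = tj.reconstruct_trajectory(body, z, tj.find_orientation_windows(body))
        sp = tj.compute_spatial_params(traj, es)
        assert sp.height == pytest.approx(2 * syn.STAIRCASES["A"][0], abs=0.02)

    def test_quaternions_unit_norm_and_no_position_jumps(self, ascending_walk_nf):
        body, tr = align_foot(ascending_walk_nf, "right")
        es = ev.detect_events(body, truth_border_set(tr))
        z = tj.detect_zupt(body, es)
        traj = tj.reconstruct_trajectory(body, z, tj.find_orientation_windows(body))
        assert np.abs(np.linalg.norm(traj.orientation, axis=1) - 1).max() < 1e-9
        # discontinuity suppression: position increments agree with the
        # velocity estimate (no jumps beyond genuine motion)
        dt = 1.0 / traj.sampling_rate
        vel_mid = 0.5 * (traj.velocity[:-1] + traj.velocity[1:]) * dt
        excess = np.linalg.norm(np.diff(traj.position, axis=0) - vel_mid, axis=1)
        assert excess.max() < 0.002
        # and at subsequence stitch points the foot is static: tiny increments
        for a, b in traj.subsequence_bounds[1:]:
            assert np.linalg.norm(traj.position[a] - traj.position[a - 1]) < 0.001

    def test_speed_small_at_zupt_run_centres(self, level_walk_nf):
        body, tr = align_foot(level_walk_nf, "right")
        es = ev.detect_events(body, truth_border_set(tr))
        z = tj.detect_zupt(body, es)
        traj = tj.reconstruct_trajectory(body, z, tj.find_orientation_windows(body))
        mask = traj.zupt
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
        for a, b in zip(edges[::2], edges[1::2]):
            centre = (a + b) // 2
            assert np.linalg.norm(traj.velocity[centre]) < 0.05

    def test_requires_an_orientation_update(self):
        seq = _static_seq(100)
        with pytest.raises(ValueError):
            tj.reconstruct_trajectory(seq, tj.detect_zupt(seq), [])


class TestSpatialParams:
    def _events_at(self, ms_list):
        return GaitEventSet(
            events=[StrideEvents(tc=m - 10, ic=m - 5, ms=m) for m in ms_list],
            sampling_rate=FS,
        )

    def _traj(self, positions, n):
        pos = np.zeros((n, 3))
        for i, p in positions.items():
            pos[i] = p
        return tj.TrajectoryEstimate(
            position=pos,
            velocity=np.zeros((n, 3)),
            orientation=np.tile([0, 0, 0, 1.0], (n, 1)),
            zupt=np.zeros(n, dtype=bool),
            sampling_rate=FS,
        )

    def test_pythagorean_example(self):
        traj = self._traj({100: [0, 0, 0], 300: [0.4, 0.3, 0.35]}, 400)
        sp = tj.compute_spatial_params(traj, self._events_at([100, 300]))
        assert sp.length[0] == pytest.approx(0.5)
        assert sp.height[0] == pytest.approx(0.35)
        assert sp.inclination[0] == pytest.approx(np.degrees(np.arctan(0.7)), abs=1e-6)
        assert sp.inclination[0] == pytest.approx(34.99, abs=0.01)

    def test_zero_length_with_height_is_flagged_90_degrees(self):
        traj = self._traj({100: [0, 0, 0], 300: [0, 0, 0.2]}, 400)
        sp = tj.compute_spatial_params(traj, self._events_at([100, 300]))
        assert sp.inclination[0] == pytest.approx(90.0)
        assert sp.flagged[0]

    def test_zero_height_gives_zero_inclination(self):
        traj = self._traj({100: [0, 0, 0], 300: [1.0, 0, 0]}, 400)
        sp = tj.compute_spatial_params(traj, self._events_at([100, 300]))
        assert sp.inclination[0] == 0.0


class TestInclinationFormula:
    def test_staircase_a_double_step_geometry(self):
        # height 2 x 17.5 cm, length 2 x 26.5 cm
        assert tj.stride_inclination_deg(0.35, 0.53) == pytest.approx(33.4, abs=0.05)

    def test_staircase_b_double_step_geometry(self):
        # height 2 x 14.5 cm, length 2 x 35 cm
        assert tj.stride_inclination_deg(0.29, 0.70) == pytest.approx(22.5, abs=0.05)
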