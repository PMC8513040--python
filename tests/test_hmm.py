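"""Feature extraction, sub-model training, assembly, decoding and border logic."""

import numpy as np
import pytest

from stairgait import hmm
from stairgait import synthetic as syn
from stairgait.types import (
    ASCENDING,
    DESCENDING,
    LEVEL,
    TRANSITION,
    DegenerateInputError,
    ImuSequence,
    Stride,
    StrideBorderSet,
)

from conftest import align_foot, truth_border_set

FS = 204.8


def _body_seq(gyr_ml: np.ndarray, acc_si: np.ndarray) -> ImuSequence:
    n = len(gyr_ml)
    gyr = np.zeros((n, 3))
    gyr[:, 0] = gyr_ml
    acc = np.zeros((n, 3))
    acc[:, 2] = acc_si
    return ImuSequence(acc=acc, gyr=gyr, sampling_rate=FS, frame="body")


class TestFeatureExtraction:
    def test_downsampling_by_four(self):
        rng = np.random.default_rng(0)
        seq = _body_seq(rng.normal(size=2048), rng.normal(size=2048) + 1)
        feats = hmm.extract_features(seq)
        assert feats.data.shape == (512, 4)
        assert feats.rate == pytest.approx(51.2)

    def test_linear_ramp_has_constant_gradient(self):
        n = 4096
        ramp = np.linspace(0, 100, n)  # dps over n samples
        rng = np.random.default_rng(1)
        seq = _body_seq(ramp, rng.normal(1, 0.3, n))
        feats = hmm.extract_features(seq)
        # before standardization the gradient column is the ramp slope; after
        # z-scoring a constant-plus-edge-effects column has tiny interior spread
        grad = feats.data[:, 2] * feats.std[2] + feats.mean[2]
        slope_per_s = 100 / (n / FS)
        interior = grad[50:-50]
        assert interior == pytest.approx(slope_per_s, rel=0.01)

    def test_gradient_matches_windowed_regression_oracle(self):
        walk = syn.generate_walk([syn.level_spec()] * 4, seed=3)
        body, _ = align_foot(walk, "left")
        feats = hmm.extract_features(body)
        # recompute the gyr gradient column with an independent per-window polyfit
        from scipy import signal as sps

        rate = FS / 4
        sos = sps.butter(4, 10, btype="low", fs=rate, output="sos")
        gyr = sps.sosfiltfilt(sos, body.gyr[::4, 0])
        w = int(round(0.2 * rate))
        w += w % 2 == 0
        half = w // 2
        idx = np.arange(half, len(gyr) - half, 7)
        oracle = [
            np.polyfit(np.arange(-half, half + 1), gyr[i - half : i + half + 1], 1)[0] * rate
            for i in idx
        ]
        grad = feats.data[:, 2] * feats.std[2] + feats.mean[2]
        assert grad[idx] == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_zero_variance_column_is_reported(self):
        seq = _body_seq(np.zeros(1024), np.ones(1024))
        with pytest.raises(DegenerateInputError, match="gyr_ml"):
            hmm.extract_features(seq)

    def test_sensor_frame_input_rejected(self):
        seq = ImuSequence(
            acc=np.zeros((100, 3)), gyr=np.zeros((100, 3)), sampling_rate=FS, frame="sensor"
        )
        with pytest.raises(ValueError):
            hmm.extract_features(seq)


class TestTopologies:
    def test_left_right_is_chain_with_self_loops(self):
        t = hmm.initial_transmat(hmm.stride_submodel_spec(LEVEL, n_states=6))
        expected_nonzero = {(i, i) for i in range(6)} | {(i, i + 1) for i in range(5)}
        assert set(zip(*np.nonzero(t))) == expected_nonzero
        assert t.sum(axis=1) == pytest.approx(np.ones(6))

    def test_transition_topology_pattern(self):
        t = hmm.initial_transmat(hmm.transition_submodel_spec(5))
        allowed = (
            {(0, j) for j in range(5)}
            | {(i, 0) for i in range(5)}
            | {(i, i) for i in range(5)}
            | {(i, i + 1) for i in range(4)}
        )
        assert set(zip(*np.nonzero(t))) <= allowed
        assert (t[0] > 0).all() and (t[:, 0] > 0).all()
        assert t[4, 4] > 0
        assert t.sum(axis=1) == pytest.approx(np.ones(5))


class TestSubmodelTraining:
    def test_single_state_single_component_learns_sample_mean(self):
        rng = np.random.default_rng(5)
        data = rng.normal([1.0, -2.0, 0.5, 3.0], 0.3, size=(400, 4))
        spec = hmm.SubModelSpec(LEVEL, n_states=1, topology="left_right", n_mixture_components=1)
        sub = hmm.train_submodel([data], spec, seed=0)
        assert sub.means[0, 0] == pytest.approx(data.mean(axis=0), abs=1e-6)

    def test_structural_zeros_preserved_by_training(self, trained_model):
        lo, hi = trained_model.block_slices[LEVEL]
        block = trained_model.transmat[lo:hi, lo:hi]
        n = hi - lo
        for i in range(n):
            for j in range(n):
                if j not in (i, i + 1) and not (i == n - 1):
                    assert block[i, j] == 0.0

    def test_loglikelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(6)
        seqs = [rng.normal(size=(60, 4)) + np.linspace(0, 3, 60)[:, None] for _ in range(6)]
        spec = hmm.SubModelSpec(LEVEL, n_states=4, topology="left_right", n_mixture_components=2)
        sub = hmm.train_submodel(seqs, spec, seed=0)
        hist = sub.log_likelihood_history
        assert len(hist) == spec.n_training_iterations
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_sequence_shorter_than_states_rejected(self):
        spec = hmm.SubModelSpec(LEVEL, n_states=20, topology="left_right")
        with pytest.raises(ValueError, match="n_states"):
            hmm.train_submodel([np.zeros((10, 4))], spec, seed=0)

    def test_toy_three_state_parameter_recovery(self):
        """Means of a 3-state chain are recovered from simulated sequences."""
        rng = np.random.default_rng(7)
        true_means = np.array([[-2.0], [0.0], [2.0]])
        seqs = []
        for _ in range(50):
            parts = [rng.normal(m, 0.2, size=(12, 1)) for m in true_means.ravel()]
            seqs.append(np.vstack(parts))
        spec = hmm.SubModelSpec(LEVEL, n_states=3, topology="left_right", n_mixture_components=1)
        sub = hmm.train_submodel(seqs, spec, seed=0)
        assert sub.means[:, 0, 0] == pytest.approx(true_means.ravel(), abs=0.2)


class TestAssembly:
    def test_dimension_is_sum_of_submodels(self, trained_model):
        assert trained_model.n_states == 5 + 20 + 20 + 20
        assert trained_model.transmat.shape == (65, 65)

    def test_rows_stochastic(self, trained_model):
        assert np.abs(trained_model.transmat.sum(axis=1) - 1).max() < 1e-9

    def test_border_edges_present_and_no_extras(self, trained_model):
        m = trained_model
        t_states = set(range(*m.block_slices[TRANSITION]))
        first = {c: m.block_slices[c][0] for c in (LEVEL, ASCENDING, DESCENDING)}
        last = {c: m.block_slices[c][1] - 1 for c in (LEVEL, ASCENDING, DESCENDING)}
        # every border edge carries probability mass
        for (i, j) in m.border_edges:
            assert m.transmat[i, j] > 0
        # no ascending <-> descending edge exists
        assert (last[ASCENDING], first[DESCENDING]) not in m.border_edges
        assert m.transmat[last[ASCENDING], first[DESCENDING]] == 0.0
        assert m.transmat[last[DESCENDING], first[ASCENDING]] == 0.0
        # zeros outside blocks + border edges
        for c in (LEVEL, ASCENDING, DESCENDING):
            lo, hi = m.block_slices[c]
            for row in range(lo, hi - 1):  # non-final stride states leave only within block
                outside = np.delete(m.transmat[row], np.arange(lo, hi))
                assert np.abs(outside).max() == 0.0
        # gait initiation from every transition state
        for t in t_states:
            for c in (LEVEL, ASCENDING, DESCENDING):
                assert (t, first[c]) in m.border_edges

    def test_missing_submodel_rejected(self, trained_model):
        with pytest.raises(ValueError, match="missing"):
            hmm.build_segmentation_model(None, None, None, None)


def _gmm_log_likelihood(x, weights, means, covars):
    """Independent diagonal-GMM log density for the enumeration oracle."""
    n_mix = weights.shape[0]
    comps = []
    for c in range(n_mix):
        var = covars[c]
        ll = -0.5 * (np.log(2 * np.pi * var).sum() + (((x - means[c]) ** 2) / var).sum())
        comps.append(np.log(weights[c]) + ll)
    m = max(comps)
    return m + np.log(sum(np.exp(c - m) for c in comps))


class TestViterbiOracle:
    @pytest.mark.parametrize("n_states,n_obs,seed", [(3, 8, 0), (4, 10, 1), (5, 6, 2), (2, 10, 3)])
    def test_decode_equals_exhaustive_enumeration(self, n_states, n_obs, seed):
        """The decoded state path maximizes the joint likelihood over all paths."""
        import itertools

        rng = np.random.default_rng(seed)
        transmat = rng.dirichlet(np.ones(n_states), size=n_states)
        startprob = rng.dirichlet(np.ones(n_states))
        weights = np.full((n_states, 2), 0.5)
        means = rng.normal(0, 2, size=(n_states, 2, 2))
        covars = np.full((n_states, 2, 2), 0.5)
        model = hmm._as_gmmhmm(startprob, transmat, weights, means, covars)
        x = rng.normal(0, 2, size=(n_obs, 2))
        _, path = model.decode(x, algorithm="viterbi")

        log_b = np.array(
            [[_gmm_log_likelihood(x[t], weights[s], means[s], covars[s]) for s in range(n_states)]
             for t in range(n_obs)]
        )
        best_ll, best_path = -np.inf, None
        for cand in itertools.product(range(n_states), repeat=n_obs):
            ll = np.log(startprob[cand[0]]) + log_b[0, cand[0]]
            for t in range(1, n_obs):
                ll += np.log(transmat[cand[t - 1], cand[t]]) + log_b[t, cand[t]]
            if ll > best_ll:
                best_ll, best_path = ll, cand
        assert tuple(path) == best_path


class TestPrediction:
    def test_transition_only_signal_has_no_strides(self, trained_model):
        """Quiet standing with sensor noise (no gait) yields an empty border set."""
        rng = np.random.default_rng(40)
        n = int(8 * FS)
        body = ImuSequence(
            acc=np.tile([0, 0, 1.0], (n, 1)) + rng.normal(0, 0.01, (n, 3)),
            gyr=rng.normal(0, 0.5, (n, 3)),
            sampling_rate=FS,
            frame="body",
        )
        feats = hmm.extract_features(body)
        borders = hmm.postprocess_strides(
            hmm.predict_stride_borders(trained_model, feats, body), body
        )
        assert len(borders) == 0

    def test_ten_stride_bout_borders_within_100ms(self, trained_model):
        specs = [syn.level_spec()] * 6 + [syn.stair_spec("B", "up")] * 8 + [syn.level_spec()] * 6
        walk = syn.generate_walk(specs, seed=41)
        tol = int(0.1 * FS)
        for foot in ("left", "right"):
            body, tr = align_foot(walk, foot)
            feats = hmm.extract_features(body)
            pred = hmm.postprocess_strides(
                hmm.predict_stride_borders(trained_model, feats, body), body
            )
            truth = tr.stride_borders
            assert len(pred) == len(truth)
            for s, (a, b) in zip(pred.strides, truth):
                assert abs(s.start - a) <= tol and abs(s.end - b) <= tol

    def test_refinement_moves_borders_at_most_150ms(self, trained_model):
        walk = syn.generate_walk([syn.level_spec()] * 8, seed=42)
        body, _ = align_foot(walk, "right")
        feats = hmm.extract_features(body)
        path = hmm.viterbi_path(trained_model, feats)
        crossings = [
            (t + 1) * hmm.DOWNSAMPLE_FACTOR
            for t in range(len(path) - 1)
            if (int(path[t]), int(path[t + 1])) in trained_model.border_edges
        ]
        pred = hmm.predict_stride_borders(trained_model, feats, body)
        half = int(round(0.15 * FS))
        snapped = sorted({s.start for s in pred.strides} | {s.end for s in pred.strides})
        for b in snapped:
            assert min(abs(b - c) for c in crossings) <= half


class TestPostprocess:
    def _borders(self, strides):
        return StrideBorderSet([Stride(*s) for s in strides], stage="refined", sampling_rate=FS)

    def _seq_with(self, dip_dps, swing_dps, start=500, end=700, n=1500):
        g = np.zeros(n)
        g[start] = dip_dps
        g[(start + end) // 2] = swing_dps
        return _body_seq(g, np.ones(n))

    def test_shallow_dip_removed(self):
        seq = self._seq_with(-15.0, 100.0)
        out = hmm.postprocess_strides(self._borders([(500, 700)]), seq)
        assert len(out) == 0

    def test_duration_bounds(self):
        seq = self._seq_with(-30.0, 60.0, start=500, end=560)  # 0.29 s: too short
        assert len(hmm.postprocess_strides(self._borders([(500, 560)]), seq)) == 0
        seq2 = self._seq_with(-30.0, 60.0, start=500, end=705)  # 1.0 s: kept
        assert len(hmm.postprocess_strides(self._borders([(500, 705)]), seq2)) == 1

    def test_weak_swing_removed(self):
        seq = self._seq_with(-30.0, 40.0)
        assert len(hmm.postprocess_strides(self._borders([(500, 700)]), seq)) == 0

    def test_empty_input_empty_output(self):
        seq = self._seq_with(-30.0, 60.0)
        out = hmm.postprocess_strides(self._borders([]), seq)
        assert len(out) == 0 and out.stage == "filtered"

    def test_filtered_is_subset_of_refined(self, trained_model):
        walk = syn.generate_walk([syn.level_spec("fast")] * 8, seed=43)
        body, _ = align_foot(walk, "left")
        feats = hmm.extract_features(body)
        refined = hmm.predict_stride_borders(trained_model, feats, body)
        filtered = hmm.postprocess_strides(refined, body)
        refined_set = {(s.start, s.end) for s in refined.strides}
        assert all((s.start, s.end) in refined_set for s in filtered.strides)


class TestPersistence:
    def test_save_load_round_trip(self, trained_model, tmp_path):
        p = tmp_path / "model.json"
        trained_model.save(p)
        loaded = hmm.SegmentationModel.load(p)
        assert np.array_equal(loaded.transmat, trained_model.transmat)
        assert np.array_equal(loaded.means, trained_model.means)
        assert loaded.border_edges == trained_model.border_edges
        assert loaded.state_class_map == trained_model.state_class_map
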