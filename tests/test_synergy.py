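"""EMG envelopes, epoching, the concatenated matrix and NMF."""

import numpy as np
import pytest

from synkin import (
    DataError,
    EmgMatrix,
    EnvelopeConfig,
    EventError,
    ParameterError,
    StructuralError,
    TaskManifest,
    TimeSeries,
    UndefinedStatisticError,
    build_matrix,
    compute_envelope,
    extract_epoch,
    nmf_decompose,
    r_squared,
    select_order,
)

RATE = 2000.0


def _emg(values):
    labels = tuple(f"m{i}" for i in range(np.atleast_2d(values).shape[0]))
    return TimeSeries(values, RATE, labels)


class TestEnvelope:
    def test_zero_signal(self):
        env = compute_envelope(_emg(np.zeros((2, 8000))))
        np.testing.assert_allclose(env.values, 0.0)
        assert np.all(env.values >= 0)

    def test_dc_offset_rejected(self):
        # constant 1.0 is removed by the 10 Hz high-pass
        env = compute_envelope(_emg(np.full((1, int(RATE * 4)), 1.0)))
        inner = env.values[0, int(RATE) : -int(RATE)]
        assert np.max(np.abs(inner)) < 1e-3

    def test_sinusoid_steady_state_two_over_pi(self):
        # rectified unit sine has mean 2/pi; the 5 Hz low-pass keeps the mean
        # and rejects the ripple harmonics at 200 Hz and above
        t = np.arange(int(RATE * 6)) / RATE
        env = compute_envelope(_emg(np.sin(2 * np.pi * 100 * t)[None, :]))
        mid = env.values[0, int(RATE) : -int(RATE)]
        assert np.mean(mid) == pytest.approx(2 / np.pi, rel=0.05)

    def test_rate_too_low(self):
        low = TimeSeries(np.zeros((1, 400)), 30.0, ("m0",))
        with pytest.raises(ParameterError):
            compute_envelope(low)


class TestExtractEpoch:
    def _env(self, value=0.5, duration_s=5.0, channels=3):
        n = int(RATE * duration_s)
        return _emg(np.full((channels, n), value))

    def test_window_arithmetic_and_shape(self):
        epoch, clamped = extract_epoch(self._env(), 1.0, 2.0)
        assert epoch.shape == (3, 100)
        assert not clamped

    def test_clamped_at_recording_start(self):
        epoch, clamped = extract_epoch(self._env(), 0.1, 1.0)
        assert clamped
        assert epoch.shape == (3, 100)

    def test_constant_envelope_gives_constant_epoch(self):
        epoch, _ = extract_epoch(self._env(0.5), 1.0, 2.0)
        np.testing.assert_allclose(epoch, 0.5)

    def test_window_outside_recording(self):
        with pytest.raises(EventError):
            extract_epoch(self._env(duration_s=2.0), 5.0, 6.0)

    def test_inverted_event_rejected(self):
        with pytest.raises(EventError):
            extract_epoch(self._env(), 2.0, 1.0)


def _manifest(n_sets=2, n_reps=2):
    from synkin import SET_TYPES

    return TaskManifest(
        tuple(
            (s, r)
            for s in SET_TYPES[:n_sets]
            for r in range(1, n_reps + 1)
        )
    )


class TestBuildMatrix:
    def test_full_protocol_dimensions(self, rng):
        # 16 muscles, 9 set types, 10 repetitions, 100 samples -> 16 x 9000
        manifest = _manifest(9, 10)
        epochs = {key: rng.random((16, 100)) + 0.01 for key in manifest.entries}
        mat = build_matrix(epochs, manifest)
        assert mat.values.shape == (16, 9000)
        assert len(mat.column_index) == 9000
        np.testing.assert_allclose(mat.values.max(axis=1), 1.0)

    def test_row_rescaled_by_global_max(self):
        manifest = TaskManifest((("quick", 1),))
        epoch = np.array([[2.0, 1.0, 0.5], [1.0, 0.25, 0.5]])
        mat = build_matrix({("quick", 1): epoch}, manifest)
        np.testing.assert_allclose(mat.values[0], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(mat.values[1], [1.0, 0.25, 0.5])

    def test_silent_channel_named_in_error(self, rng):
        manifest = _manifest(1, 2)
        epochs = {key: rng.random((3, 10)) + 0.1 for key in manifest.entries}
        for key in epochs:
            epochs[key][1] = 0.0
        with pytest.raises(DataError, match="ch2"):
            build_matrix(epochs, manifest)

    def test_missing_epoch_rejected(self, rng):
        manifest = _manifest(1, 2)
        epochs = {manifest.entries[0]: rng.random((3, 10))}
        with pytest.raises(StructuralError):
            build_matrix(epochs, manifest)

    def test_column_index_in_manifest_order(self, rng):
        manifest = _manifest(2, 1)
        epochs = {key: rng.random((2, 4)) + 0.1 for key in manifest.entries}
        mat = build_matrix(epochs, manifest)
        assert list(mat.column_index["set_type"].unique()) == [
            s for s, _ in manifest.entries
        ]


class TestRSquared:
    def test_perfect_reconstruction(self, rng):
        W = rng.random((4, 2))
        C = rng.random((2, 30))
        assert r_squared(W @ C, W, C) == pytest.approx(1.0)

    def test_row_mean_reconstruction_is_zero(self, rng):
        V = rng.random((4, 30))
        means = V.mean(axis=1, keepdims=True)
        # W C = row-mean matrix via W = means, C = ones
        assert r_squared(V, means, np.ones((1, 30))) == pytest.approx(0.0, abs=1e-12)

    def test_direct_summation_oracle(self):
        V = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0]])
        W = np.array([[1.0], [0.8]])
        C = np.array([[1.0, 2.0, 2.5, 3.5]])
        recon = W @ C
        sse = sum(
            (V[i, j] - recon[i, j]) ** 2 for i in range(2) for j in range(4)
        )
        sst = sum(
            (V[i, j] - V[i].sum() / 4) ** 2 for i in range(2) for j in range(4)
        )
        assert r_squared(V, W, C) == pytest.approx(1 - sse / sst, abs=1e-14)

    def test_constant_matrix_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared(np.ones((3, 5)), np.ones((3, 1)), np.ones((1, 5)))

    def test_shape_mismatch(self, rng):
        with pytest.raises(StructuralError):
            r_squared(rng.random((3, 5)), rng.random((3, 2)), rng.random((2, 4)))


class TestNmf:
    def test_rank_one_recovery(self, rng):
        w = rng.random(6) + 0.2
        c = rng.random(200) + 0.1
        model = nmf_decompose(np.outer(w, c), 1, n_restarts=3, seed=0)
        assert model.r_squared >= 0.999
        cos = float(
            w @ model.W[:, 0] / (np.linalg.norm(w) * np.linalg.norm(model.W[:, 0]))
        )
        assert cos >= 0.999

    def test_determinism_bitwise(self, rng):
        V = rng.random((5, 80))
        a = nmf_decompose(V, 3, n_restarts=4, seed=99)
        b = nmf_decompose(V, 3, n_restarts=4, seed=99)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.C, b.C)
        assert a.restart_seeds == b.restart_seeds

    def test_full_order_at_least_as_good(self, rng):
        V = rng.random((5, 60))
        low = nmf_decompose(V, 2, n_restarts=5, seed=1)
        full = nmf_decompose(V, 5, n_restarts=5, seed=1)
        assert full.r_squared >= low.r_squared - 1e-6

    def test_outputs_non_negative_and_normalized(self, rng):
        V = rng.random((6, 100))
        model = nmf_decompose(V, 3, n_restarts=3, seed=5)
        assert np.all(model.W >= 0)
        assert np.all(model.C >= 0)
        np.testing.assert_allclose(
            np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10
        )

    def test_normalization_preserves_reconstruction(self, rng):
        # reconstruct with un-normalized factors fitted on the same data
        from synkin.synergy import _mu_nmf, _normalize

        V = rng.random((6, 80))
        W, H, _, _ = _mu_nmf(V, 3, np.random.default_rng(0), 1e-6, 200)
        Wn, Hn = _normalize(W, H)
        assert np.max(np.abs(W @ H - Wn @ Hn)) < 1e-10

    def test_negative_data_rejected(self):
        with pytest.raises(DataError):
            nmf_decompose(np.array([[1.0, -0.1]]), 1)

    def test_not_worse_than_sklearn_reference(self, rng):
        # independent reference implementation on the same problem
        sklearn = pytest.importorskip("sklearn.decomposition")
        W = rng.random((8, 3)) + 0.05
        C = rng.random((3, 150)) + 0.05
        V = W @ C + 0.01 * rng.random((8, 150))
        ours = nmf_decompose(V, 3, n_restarts=10, seed=2)
        ref = sklearn.NMF(
            n_components=3, init="random", solver="mu", max_iter=2000,
            random_state=0, tol=1e-9,
        )
        Wr = ref.fit_transform(V)
        r2_ref = r_squared(V, Wr, ref.components_)
        assert ours.r_squared >= r2_ref - 0.01


class TestSelectOrder:
    def test_noiseless_rank3_with_high_threshold(self, rng):
        # three synergies with distinct muscle supports and separated
        # activation bumps: lower orders cannot reach the threshold, the
        # exact rank does
        W = np.zeros((6, 3))
        W[[0, 1], 0] = [0.9, 0.7]
        W[[2, 3], 1] = [0.8, 0.8]
        W[[4, 5], 2] = [0.7, 0.9]
        t = np.linspace(0.0, 1.0, 300)
        C = np.vstack(
            [np.exp(-0.5 * ((t - c) / 0.06) ** 2) for c in (0.2, 0.5, 0.8)]
        )
        curve = select_order(W @ C, threshold=0.95, n_restarts=5, seed=0)
        assert curve.selected_order == 3
        assert curve.r_squared_per_order[2] >= 0.95

    def test_tiny_threshold_selects_order_one(self, rng):
        V = rng.random((4, 50))
        curve = select_order(V, threshold=1e-9, n_restarts=2, seed=0)
        assert curve.selected_order == 1

    def test_unreachable_threshold_warns_and_selects_full(self, rng):
        V = rng.random((4, 200))  # full-rank noise never fits exactly
        with pytest.warns(UserWarning, match="no order reached"):
            curve = select_order(V, threshold=1.0, n_restarts=2, seed=0)
        assert curve.selected_order == 4

    def test_threshold_validated(self, rng):
        with pytest.raises(ParameterError):
            select_order(rng.random((3, 10)), threshold=0.0)

    def test_curve_non_decreasing_within_tolerance(self, rng):
        W = rng.random((6, 3)) + 0.1
        C = rng.random((3, 200)) + 0.05
        V = W @ C + 0.05 * rng.random((6, 200))
        curve = select_order(V, n_restarts=5, seed=3)
        r = np.array(curve.r_squared_per_order)
        assert np.all(np.diff(r) >= -0.01)
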