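"""Segmentation, profile averaging and ROM summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synkin import (
    ParameterError,
    SegmentationConfig,
    StructuralError,
    TimeSeries,
    average_profiles,
    compute_rom,
    derivative,
    rom_summary,
    segment_repetitions,
)
from conftest import bump_trace


class TestDerivative:
    def test_constant_is_zero(self):
        np.testing.assert_allclose(derivative(np.full(50, 3.0), 100.0), 0.0)

    def test_linear_ramp(self):
        # 1 degree per sample at 100 Hz -> 100 deg/s everywhere
        d = derivative(np.arange(50, dtype=float), 100.0)
        np.testing.assert_allclose(d, 100.0)

    def test_sinusoid_matches_finite_difference_oracle(self):
        # independent oracle: analytic central difference of sin(2*pi*f*t)
        rate, f = 100.0, 2.0
        t = np.arange(500) / rate
        x = np.sin(2 * np.pi * f * t)
        d = derivative(x, rate)
        h = 1.0 / rate
        oracle = (np.sin(2 * np.pi * f * (t + h)) - np.sin(2 * np.pi * f * (t - h))) / (
            2 * h
        )
        np.testing.assert_allclose(d[1:-1], oracle[1:-1], atol=1e-9)
        # and the truncation error vs the true derivative is bounded by
        # (2*pi*f)^3 h^2 / 6
        true = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 * h**2 / 6
        assert np.max(np.abs(d[1:-1] - true[1:-1])) <= bound * 1.01

    def test_too_short(self):
        with pytest.raises(ParameterError):
            derivative([1.0], 100.0)


class TestSegmentation:
    def test_constant_trace_yields_no_events(self):
        events = segment_repetitions(np.full(1000, 30.0), 100.0)
        assert len(events) == 0

    def test_single_raised_cosine_bump(self):
        # amplitude 80 deg, rising 4->5 s, falling 5->6 s in a 10 s trace
        x = bump_trace([4.0], [2.0], amplitude=80.0, total_s=10.0)
        events = segment_repetitions(x, 100.0)
        assert len(events) == 1
        assert events.onsets_s()[0] == pytest.approx(4.0, abs=0.05)
        assert events.offsets_s()[0] == pytest.approx(6.0, abs=0.05)

    def test_ten_identical_bumps(self):
        onsets = 2.0 + 3.0 * np.arange(10)
        x = bump_trace(onsets, 2.0)
        events = segment_repetitions(x, 100.0)
        assert len(events) == 10
        np.testing.assert_allclose(events.onsets_s(), onsets, atol=0.05)
        np.testing.assert_allclose(events.offsets_s(), onsets + 2.0, atol=0.05)

    def test_pairs_ordered_and_non_overlapping(self):
        x = bump_trace([1.0, 4.0, 7.5], [1.5, 2.0, 1.8])
        events = segment_repetitions(x, 100.0)
        flat = [i for pair in events.pairs for i in pair]
        assert flat == sorted(flat)
        assert len(set(flat)) == len(flat)

    def test_unpaired_final_flexion_clamped_and_flagged(self):
        # rising half-bump at the very end: no falling phase in the trace
        rate = 100.0
        x = np.full(800, 20.0)
        u = np.linspace(0.0, 0.5, 200)
        x[600:] += 80 * 0.5 * (1 - np.cos(2 * np.pi * u))
        events = segment_repetitions(x, rate)
        assert len(events) == 1
        assert events.clamped[0]
        assert events.pairs[0][1] == len(x) - 1

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_planted_events_recovered_with_noise(self, seed):
        rng = np.random.default_rng(seed)
        n_events = int(rng.integers(2, 6))
        durations = rng.uniform(1.5, 2.5, n_events)
        gaps = rng.uniform(1.0, 2.0, n_events)
        onsets = 1.5 + np.cumsum(gaps + durations) - durations
        amp = rng.uniform(20.0, 90.0)
        x = bump_trace(onsets, durations, amplitude=amp, baseline=20.0)
        # execution variability concentrated in the movement itself (rest
        # angles are essentially flat in sensor-derived joint traces)
        window = (x - 20.0) / amp
        x = x + 0.03 * amp * window * rng.standard_normal(x.size)
        events = segment_repetitions(x, 100.0)
        assert len(events) == n_events
        np.testing.assert_allclose(events.onsets_s(), onsets, atol=0.05)
        np.testing.assert_allclose(
            events.offsets_s(), onsets + durations, atol=0.05
        )

    def test_threshold_fraction_validated(self):
        with pytest.raises(ParameterError):
            SegmentationConfig(threshold_fraction=1.5)


def _trial(values, labels=("shoulder_fe", "elbow_fe")):
    return TimeSeries(np.asarray(values, dtype=float), 100.0, labels)


class TestAverageProfiles:
    def test_identical_repetitions_mean_equals_any_sd_zero(self):
        rep = _trial(np.random.default_rng(0).random((2, 40)))
        prof = average_profiles([rep] * 10)
        np.testing.assert_allclose(prof.mean, rep.values)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)

    def test_output_length_is_longest(self):
        short = _trial(np.zeros((2, 100)))
        long = _trial(np.zeros((2, 200)))
        prof = average_profiles([short, long])
        assert prof.mean.shape == (2, 200)

    def test_two_constant_repetitions_hand_computed(self):
        a = _trial(np.full((2, 50), 10.0))
        b = _trial(np.full((2, 50), 20.0))
        prof = average_profiles([a, b])
        np.testing.assert_allclose(prof.mean, 15.0)
        np.testing.assert_allclose(prof.sd, np.sqrt(50.0))

    def test_mismatched_channels_rejected(self):
        a = _trial(np.zeros((2, 50)))
        b = _trial(np.zeros((2, 50)), labels=("x", "y"))
        with pytest.raises(StructuralError):
            average_profiles([a, b])

    def test_single_repetition_sd_zero(self):
        prof = average_profiles([_trial(np.ones((2, 30)))])
        np.testing.assert_allclose(prof.sd, 0.0)


class TestRom:
    @pytest.mark.parametrize(
        "trace,expected",
        [
            (np.full(100, 5.0), 0.0),
            (np.linspace(-10.0, 150.0, 100), 160.0),
        ],
    )
    def test_examples(self, trace, expected):
        assert compute_rom(trace) == pytest.approx(expected)

    def test_raised_cosine_bump_rom_equals_amplitude(self):
        # sampling does not land exactly on the peak; tolerance covers the
        # discretization of the cosine maximum
        x = bump_trace([2.0], [2.0], amplitude=80.0, baseline=20.0)
        assert compute_rom(x) == pytest.approx(80.0, abs=0.01)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_translation_invariance_and_linear_scaling(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.random(200) * 50
        base = compute_rom(x)
        assert compute_rom(x + shift) == pytest.approx(base, abs=1e-9)
        assert compute_rom(x * scale) == pytest.approx(base * scale, rel=1e-12)

    def test_summary_against_order_statistics_oracle(self):
        rng = np.random.default_rng(3)
        trials = {
            "quick": [_trial(rng.random((2, 60)) * 90) for _ in range(9)],
            "fast": [_trial(rng.random((2, 60)) * 40) for _ in range(7)],
        }
        summary = rom_summary(trials)

        def oracle_quantile(values, q):
            # linear interpolation between order statistics, coded separately
            v = sorted(values)
            pos = q * (len(v) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        for _, row in summary.summary.iterrows():
            roms = summary.per_repetition.query(
                "set_type == @row.set_type and dof == @row.dof"
            )["rom_deg"].tolist()
            assert row["median"] == pytest.approx(oracle_quantile(roms, 0.5))
            assert row["q1"] == pytest.approx(oracle_quantile(roms, 0.25))
            assert row["q3"] == pytest.approx(oracle_quantile(roms, 0.75))
            assert row["q1"] <= row["median"] <= row["q3"]

    def test_identical_repetitions_iqr_zero(self):
        rep = _trial(np.random.default_rng(0).random((2, 60)))
        summary = rom_summary({"seven": [rep] * 5})
        assert (summary.summary["q3"] - summary.summary["q1"]).abs().max() == 0

    def test_median_of_three(self):
        reps = [
            _trial(np.vstack([np.linspace(0, r, 50)] * 2)) for r in (60, 70, 80)
        ]
        summary = rom_summary({"two": reps})
        assert set(summary.summary["median"]) == {70.0}

    def test_empty_group_warns_and_skips(self):
        rep = _trial(np.ones((2, 30)))
        with pytest.warns(UserWarning, match="no repetitions"):
            out = rom_summary({"quick": [rep], "fast": []})
        assert set(out.per_repetition["set_type"]) == {"quick"}
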