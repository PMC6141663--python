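import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiquant import (AnalysisConfig, SimulationConfig, SynapseTrace,
                       classify_synchronization, detect_response_time,
                       identify_synapses, normalize_to_nh4, peak_response,
                       simulate_syphy_movie, subtract_background,
                       summarize_synchrony)
from vesiquant.benchmarks import syphy_classification_benchmark


def _trace(times, values):
    return SynapseTrace(roi_id=0, times=np.asarray(times, float),
                        raw=np.asarray(values, float))


class TestIdentifySynapses:
    def _movie(self, **kwargs):
        cfg = SimulationConfig(n_spots=3, image_shape=(96, 96), n_frames=60,
                               frame_interval=0.5, stim_onset=5.0, seed=8,
                               bleach_tau=1e12, **kwargs)
        movie, truth = simulate_syphy_movie(cfg, surface_fraction=0.1,
                                            nh4_window=(15.0, 22.0))
        return subtract_background(movie), truth

    def test_plateau_puncta_retained(self):
        movie, truth = self._movie()
        rois = identify_synapses(movie, (15.0, 22.0))
        assert len(rois) == len(truth.spots)

    def test_punctum_without_plateau_rejected(self):
        # surface_fraction 1: no rise on NH4 -> plateau factor < 2
        cfg = SimulationConfig(n_spots=3, image_shape=(96, 96), n_frames=60,
                               frame_interval=0.5, stim_onset=5.0, seed=8,
                               bleach_tau=1e12)
        movie, _ = simulate_syphy_movie(cfg, surface_fraction=1.0,
                                        nh4_window=(15.0, 22.0))
        movie = subtract_background(movie)
        assert identify_synapses(movie, (15.0, 22.0)) == []

    def test_drifting_punctum_rejected(self):
        from vesiquant.core_io import MovieStack
        from vesiquant.synthetic import _render_gaussian_spot

        frames = np.zeros((60, 64, 64))
        for k in range(60):
            drift = 3.0 * k / 59  # 3 px drift over the movie
            amp = 200.0 if k >= 40 else 20.0  # plateau in last third
            _render_gaussian_spot(frames[k], 32.0 + drift, 32.0, amp, 1.3)
        movie = MovieStack(frames, pixel_size=0.16, frame_interval=0.5,
                           stim_onset=5.0)
        rois = identify_synapses(movie, (15.0, 24.0))
        assert rois == []

    def test_window_outside_movie_rejected(self):
        movie, _ = self._movie()
        with pytest.raises(ValueError):
            identify_synapses(movie, (500.0, 600.0))


class TestNormalizeToNh4:
    def test_baseline_maps_to_pool_fraction(self):
        times = np.arange(20, dtype=float)
        raw = np.full(20, 50.0)
        raw[12:18] = 500.0
        out = normalize_to_nh4(_trace(times, raw), (12.0, 17.0))
        assert out.normalized[0] == pytest.approx(0.1)
        assert out.normalized[13] == pytest.approx(1.0)

    def test_constant_trace_normalizes_to_one(self):
        out = normalize_to_nh4(_trace(np.arange(10.0), np.full(10, 321.0)),
                               (5.0, 8.0))
        np.testing.assert_allclose(out.normalized, 1.0)

    def test_zero_plateau_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_nh4(_trace(np.arange(10.0), np.zeros(10)), (5.0, 8.0))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_invariant_to_expression_level(self, scale):
        """Multiplying the raw trace by any positive constant leaves the
        normalized trace unchanged — the purpose of pool normalization."""
        times = np.arange(30, dtype=float)
        rng = np.random.default_rng(4)
        raw = 50.0 + 10 * rng.random(30)
        raw[20:25] = 500.0
        a = normalize_to_nh4(_trace(times, raw), (20.0, 24.0))
        b = normalize_to_nh4(_trace(times, raw * scale), (20.0, 24.0))
        np.testing.assert_allclose(a.normalized, b.normalized, rtol=1e-12)


class TestDetectResponseTime:
    def _noisy_baseline_trace(self, step_at=None, step=10.0, spike_at=None):
        # bounded alternating ripple: fluctuation with a known SD that can
        # never cross the 2xSD threshold on its own
        times = np.arange(-10.0, 10.0, 0.2)
        vals = 100.0 + 0.5 * np.where(np.arange(len(times)) % 2 == 0, 1.0, -1.0)
        if step_at is not None:
            vals[times >= step_at] += step
        if spike_at is not None:
            k = int(np.argmin(np.abs(times - spike_at)))
            vals[k] += step
        return _trace(times, vals)

    def test_step_detected_at_onset(self):
        tr = self._noisy_baseline_trace(step_at=0.8)
        t = detect_response_time(tr, baseline_window=(-10.0, -1.0))
        assert t == pytest.approx(0.8, abs=0.2)

    def test_flat_noise_gives_none(self):
        tr = self._noisy_baseline_trace()
        assert detect_response_time(tr, baseline_window=(-10.0, -1.0)) is None

    def test_single_frame_spike_rejected_by_sustain_rule(self):
        tr = self._noisy_baseline_trace(spike_at=2.0)
        assert detect_response_time(tr, baseline_window=(-10.0, -1.0)) is None

    def test_short_baseline_rejected(self):
        tr = _trace(np.arange(-2.0, 5.0), np.ones(7))
        with pytest.raises(ValueError):
            detect_response_time(tr, baseline_window=(-2.0, -1.0))

    def test_search_end_excludes_nh4_plateau(self):
        times = np.arange(-10.0, 30.0, 0.5)
        rng = np.random.default_rng(1)
        vals = 10.0 + rng.normal(0, 0.5, len(times))
        vals[times >= 20.0] = 100.0  # NH4 plateau only
        tr = _trace(times, vals)
        assert detect_response_time(tr, (-10.0, -1.0), search_end=20.0) is None


class TestClassification:
    @pytest.mark.parametrize("t,expected", [
        (0.8, "synchronized"),          # within 1 s of stimulus onset
        (-3.0, "pre_stimulus"),         # responding before stimulation
        (5.0, "delayed"),
        (None, "nonresponsive"),
        (0.0, "synchronized"),
        (1.0, "synchronized"),
    ])
    def test_examples(self, t, expected):
        assert classify_synchronization(t, sync_window=1.0) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.one_of(st.none(),
                     st.floats(min_value=-100, max_value=100,
                               allow_nan=False)))
    def test_partition_is_exhaustive_and_exclusive(self, t):
        cls = classify_synchronization(t)
        assert cls in ("pre_stimulus", "synchronized", "delayed",
                       "nonresponsive")


class TestPeakResponse:
    def test_programmed_doubling(self):
        times = np.arange(-10.0, 30.0, 0.5)
        raw = np.where(times < 0.5, 50.0, 100.0)
        raw[times >= 20.0] = 500.0
        tr = normalize_to_nh4(_trace(times, raw), (20.0, 29.0))
        detect_response_time(tr, (-10.0, -1.0), search_end=20.0)
        assert peak_response(tr, (0.0, 15.0)) == pytest.approx(0.1)

    def test_flat_trace_near_zero(self):
        times = np.arange(-10.0, 30.0, 0.5)
        raw = np.full(len(times), 50.0)
        raw[times >= 20.0] = 500.0
        tr = normalize_to_nh4(_trace(times, raw), (20.0, 29.0))
        detect_response_time(tr, (-10.0, -1.0), search_end=20.0)
        assert peak_response(tr, (0.0, 15.0)) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_ramp_peaks_at_window_end(self):
        times = np.arange(-10.0, 30.0, 0.5)
        raw = np.interp(times, [-10.0, 19.5], [50.0, 250.0])
        raw[times >= 20.0] = 500.0
        tr = normalize_to_nh4(_trace(times, raw), (20.0, 29.0))
        tr.baseline_mean = float(tr.normalized[times < -1.0].mean())
        end_val = tr.normalized[np.argmin(np.abs(times - 15.0))]
        assert peak_response(tr, (0.0, 15.0)) == pytest.approx(
            end_val - tr.baseline_mean)


class TestSummarizeSynchrony:
    def test_fraction_arithmetic(self):
        classes = (["synchronized"] * 8 + ["pre_stimulus"] + ["delayed"])
        out = summarize_synchrony(classes)
        assert out["synchronized"] == pytest.approx(0.8)
        assert out["pre_stimulus"] == pytest.approx(0.1)
        assert out["delayed"] == pytest.approx(0.1)
        assert out["nonresponsive_fraction"] == 0.0

    def test_all_synchronized(self):
        out = summarize_synchrony(["synchronized"] * 5)
        assert out["synchronized"] == 1.0
        assert out["pre_stimulus"] == out["delayed"] == 0.0

    def test_all_nonresponsive_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            summarize_synchrony(["nonresponsive"] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_synchrony([])


class TestEndToEnd:
    def test_programmed_classes_recovered_exactly(self):
        res = syphy_classification_benchmark(n_synapses=20, seed=0)
        assert res["n_found"] == 20
        assert res["class_accuracy"] == 1.0
        assert res["max_time_error_s"] <= 0.5  # one frame at 2 Hz

    def test_pre_and_synchronized_pair(self):
        """Two synapses responding at -3 s and +0.8 s classify as
        pre_stimulus and synchronized after the full pipeline."""
        nh4 = (25.0, 35.0)
        cfg = SimulationConfig(n_spots=2, image_shape=(96, 96), n_frames=120,
                               frame_interval=0.5, stim_onset=20.0, seed=2,
                               bleach_tau=1e12)
        movie, truth = simulate_syphy_movie(cfg, 0.1, nh4,
                                            response_times=[-3.0, 0.8])
        movie = subtract_background(movie)
        from vesiquant.syphy import analyze_syphy_movie
        config = AnalysisConfig(baseline_window=(-15.0, -8.0))
        traces = analyze_syphy_movie(movie, nh4, config)
        classes = sorted(classify_synchronization(t.response_time)
                         for t in traces)
        assert classes == ["pre_stimulus", "synchronized"]
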