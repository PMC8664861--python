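import numpy as np
import pytest

from duovolt import synthgen as sg
from duovolt.network import (
    bandpass_lfp,
    classify_propagation_pattern,
    correlation_matrix,
    correlation_vs_distance,
    downsample_trace,
    recruitment_order,
    seizure_onsets,
    windowed_lfp_optical_correlation,
)
from duovolt.traces import Trace, TraceSet


def tone(freq, duration=10.0, rate=1000.0, amp=1.0):
    t = np.arange(0, duration, 1 / rate)
    return Trace(t, amp * np.sin(2 * np.pi * freq * t), kind="electrical", label="lfp")


class TestBandpassLfp:
    def test_dc_removed(self):
        tr = tone(5.0, duration=30.0)
        out = bandpass_lfp(Trace(tr.t, tr.y + 10.0, kind="electrical"))
        # judge away from the filtfilt edge transients of the 0.2 Hz edge
        assert abs(out.y[10_000:20_000].mean()) < 0.01

    def test_passband_tone_preserved(self):
        out = bandpass_lfp(tone(10.0))
        mid = slice(2000, 8000)  # avoid filter edges
        assert abs(out.y[mid].std() - tone(10.0).y[mid].std()) \
            / tone(10.0).y[mid].std() < 0.05

    def test_stopband_tone_attenuated_20db(self):
        src = tone(100.0)
        out = bandpass_lfp(src)
        mid = slice(2000, 8000)
        # compare the 100 Hz Fourier component itself; the slow edge
        # transient of the 0.2 Hz corner would otherwise dominate the std
        k = np.argmin(np.abs(np.fft.rfftfreq(6000, 1e-3) - 100.0))
        ratio = np.abs(np.fft.rfft(out.y[mid]))[k] / np.abs(np.fft.rfft(src.y[mid]))[k]
        assert ratio < 0.1  # >= 20 dB

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_lfp(tone(5.0), low=60.0, high=40.0)
        with pytest.raises(ValueError):
            bandpass_lfp(tone(5.0, rate=80.0), low=0.2, high=50.0)


class TestDownsample:
    def test_resample_then_correlate_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 1 / 1000.0)
        slow = np.convolve(rng.normal(0, 1, t.size), np.ones(200) / 200, "same")
        a = Trace(t, slow, kind="electrical")
        a30 = downsample_trace(a, 30.0)
        a30b = downsample_trace(downsample_trace(a, 120.0), 30.0)
        r = np.corrcoef(a30.y, a30b.y)[0, 1]
        assert r > 0.999


class TestCorrelationMatrix:
    def _set(self, mat, rate=30.0):
        t = np.arange(mat.shape[1]) / rate
        return TraceSet([Trace(t, row, kind="dff", label=f"r{i}")
                         for i, row in enumerate(mat)])

    def test_duplicate_traces_r_one(self, rng):
        y = rng.normal(0, 1, 300)
        m = correlation_matrix(self._set(np.stack([y, y.copy()])))
        assert np.isclose(m.r[0, 1], 1.0)

    def test_independent_noise_low_r(self, rng):
        mat = rng.normal(0, 1, (4, 5000))
        m = correlation_matrix(self._set(mat))
        off = m.r[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.1)

    def test_symmetric_unit_diagonal(self, rng):
        m = correlation_matrix(self._set(rng.normal(0, 1, (5, 200))))
        assert np.array_equal(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)
        assert np.nanmax(np.abs(m.r)) <= 1.0

    def test_constant_trace_flagged_nan(self, rng):
        mat = rng.normal(0, 1, (3, 100))
        mat[1] = 5.0
        m = correlation_matrix(self._set(mat))
        assert np.isnan(m.r[0, 1]) and np.isnan(m.r[1, 2])
        assert np.isfinite(m.r[0, 2])


class TestCorrelationVsDistance:
    def test_pair_count(self, rng):
        n = 6
        mat = rng.normal(0, 1, (n, 400))
        t = np.arange(400) / 30.0
        ts = TraceSet([Trace(t, r, kind="dff", label=f"c{i}")
                       for i, r in enumerate(mat)])
        m = correlation_matrix(ts)
        cents = {f"c{i}": (10.0 * i, 0.0) for i in range(n)}
        out = correlation_vs_distance(m, cents)
        assert out["distance"].size == n * (n - 1) // 2

    def test_synchronized_population_flat_trend(self, rng):
        shared = np.convolve(rng.normal(0, 1, 2000), np.ones(60) / 60, "same")
        mat = shared + rng.normal(0, 0.05, (6, 2000))
        t = np.arange(2000) / 30.0
        ts = TraceSet([Trace(t, r, kind="dff", label=f"c{i}")
                       for i, r in enumerate(mat)])
        m = correlation_matrix(ts)
        cents = {f"c{i}": (25.0 * i, 0.0) for i in range(6)}
        out = correlation_vs_distance(m, cents)
        assert abs(out["slope"]) < 5e-4
        assert out["mean_r"] > 0.8

    def test_spatial_decorrelation_negative_trend(self, rng):
        # correlation decays with distance by construction
        n, m_samples = 8, 3000
        base = rng.normal(0, 1, m_samples)
        mat = np.zeros((n, m_samples))
        for i in range(n):
            w = max(0.0, 1.0 - 0.13 * i)
            mat[i] = w * base + (1 - w) * rng.normal(0, 1, m_samples)
        t = np.arange(m_samples) / 30.0
        ts = TraceSet([Trace(t, r, kind="dff", label=f"c{i}")
                       for i, r in enumerate(mat)])
        cm = correlation_matrix(ts)
        cents = {f"c{i}": (30.0 * i, 0.0) for i in range(n)}
        out = correlation_vs_distance(cm, cents)
        assert out["slope"] < 0

    def test_missing_centroid_raises(self, rng):
        mat = rng.normal(0, 1, (3, 100))
        t = np.arange(100) / 30.0
        ts = TraceSet([Trace(t, r, kind="dff", label=f"c{i}")
                       for i, r in enumerate(mat)])
        with pytest.raises(KeyError):
            correlation_vs_distance(correlation_matrix(ts), {"c0": (0, 0)})


class TestWindowedLfpOpticalCorrelation:
    def test_identical_signal_peak_one_lag_zero(self, rng):
        t = np.arange(0, 30, 1 / 1000.0)
        y = np.convolve(rng.normal(0, 1, t.size), np.ones(300) / 300, "same")
        lfp = Trace(t, y, kind="electrical")
        ofp = downsample_trace(lfp, 30.0)
        out = windowed_lfp_optical_correlation(lfp, ofp, onset=25.0)
        for w in out:
            assert w["peak"] > 0.99
            assert abs(w["lag"]) <= 1 / 30.0 + 1e-9

    def test_window_escaping_recording_raises(self, rng):
        t = np.arange(0, 25, 1 / 1000.0)
        lfp = Trace(t, rng.normal(0, 1, t.size), kind="electrical")
        ofp = downsample_trace(lfp, 30.0)
        with pytest.raises(ValueError):
            windowed_lfp_optical_correlation(lfp, ofp, onset=15.0,
                                             windows=((10.0, 20.0),))


class TestSeizureOnsets:
    def test_constructed_delays(self):
        rate = 1000.0
        t = np.arange(0, 20, 1 / rate)
        rng = np.random.default_rng(0)
        lfp_y = rng.normal(0, 0.5, t.size)
        lfp_y[t >= 10.0] += 8.0 * np.sign(np.sin(2 * np.pi * 5 * t[t >= 10.0]))
        lfp = Trace(t, lfp_y, kind="electrical", label="lfp")
        t30 = np.arange(0, 20, 1 / 30.0)
        v = rng.normal(0, 0.004, t30.size)
        v[t30 >= 10.1] -= 0.03
        c = rng.normal(0, 0.004, t30.size)
        c[t30 >= 12.5] += 0.4
        ts = {"voltage": TraceSet([Trace(t30, v, kind="dff", label="cell")]),
              "calcium": TraceSet([Trace(t30, c, kind="dff", label="cell")])}
        mk = seizure_onsets(lfp, ts, sustain=0.5, baseline_window=(0.0, 5.0))
        assert abs(mk.lfp_onset - 10.0) < 0.15
        assert abs(mk.delays["voltage:cell"] - 0.1) < 0.15
        assert abs(mk.delays["calcium:cell"] - 2.5) < 0.15
        assert "cell" in mk.recruitment_times

    def test_flat_traces_flagged_absent(self, rng):
        t = np.arange(0, 20, 1 / 1000.0)
        lfp = Trace(t, rng.normal(0, 0.5, t.size), kind="electrical")
        t30 = np.arange(0, 20, 1 / 30.0)
        ts = {"voltage": TraceSet([Trace(t30, rng.normal(0, 0.004, t30.size),
                                         kind="dff", label="cell")])}
        mk = seizure_onsets(lfp, ts, sustain=1.0, baseline_window=(0.0, 5.0))
        assert mk.lfp_onset is None
        assert mk.signal_onsets["voltage:cell"] is None
        assert mk.delays["voltage:cell"] is None


class TestRecruitmentOrder:
    def test_constructed_wavefront_speed(self):
        onsets = {f"c{i}": 10.0 + 0.3 * i for i in range(6)}
        positions = {f"c{i}": (30.0 * i, 0.0) for i in range(6)}
        out = recruitment_order(onsets, positions)
        assert abs(out["speed"] - 100.0) / 100.0 < 0.01
        assert out["order"] == [f"c{i}" for i in range(6)]
        assert not out["synchronous"]

    def test_identical_onsets_flagged_synchronous(self):
        onsets = {f"c{i}": 5.0 for i in range(4)}
        positions = {f"c{i}": (20.0 * i, 0.0) for i in range(4)}
        out = recruitment_order(onsets, positions)
        assert out["synchronous"]
        assert out["speed"] == np.inf

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            recruitment_order({"a": 1.0, "b": 2.0}, {"a": (0, 0), "b": (1, 0)})

    def test_voltage_onsets_tighter_than_calcium_in_simulation(self, episode_net):
        ep = episode_net
        gt = ep.ground_truth
        assert np.std(gt.subthreshold_onsets) < np.std(gt.recruitment_times)


@pytest.fixture(scope="module")
def episode_net():
    scene = sg.default_scene(n_cells=8, seed=4)
    dyn = sg.VoltageDynamics(epsp_rate=0.0)
    sz = sg.SeizureConfig(preictal_window=20.0, focus_offset=400.0)
    return sg.simulate_seizure_episode(dyn, scene, sz, 35.0, seed=4)


class TestClassifyPropagationPattern:
    def _areas(self, onsets, n=2000, rate=30.0, amp=-0.03, noise=0.002, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / rate
        traces = []
        positions = {}
        for i, o in enumerate(onsets):
            y = rng.normal(0, noise, n)
            if o is not None:
                y[(t >= o) & (t < o + 1.0)] += amp
            traces.append(Trace(t, y, kind="dff", label=f"a{i}"))
            positions[f"a{i}"] = (20.0 * i, 0.0)
        return TraceSet(traces), positions

    def test_synchronous(self):
        ts, pos = self._areas([30.0, 30.01, 30.02, 30.0])
        out = classify_propagation_pattern(ts, (29.0, 33.0), pos)
        assert out["pattern"] == "synchronous"

    def test_propagating_left_to_right(self):
        ts, pos = self._areas([30.0, 30.3, 30.6, 30.9, 31.2, 31.5])
        out = classify_propagation_pattern(ts, (29.0, 34.0), pos)
        assert out["pattern"] == "propagating"
        assert abs(out["r"]) > 0.9

    def test_partial_activation(self):
        ts, pos = self._areas([None, None, 30.0, 30.02])
        out = classify_propagation_pattern(ts, (29.0, 33.0), pos,
                                           coverage_frac=0.8)
        assert out["pattern"] == "partial"
        assert out["active_fraction"] == 0.5

    def test_no_active_areas_raises(self):
        ts, pos = self._areas([None, None, None, None])
        with pytest.raises(ValueError):
            classify_propagation_pattern(ts, (29.0, 33.0), pos)

    def test_needs_four_areas(self):
        ts, pos = self._areas([30.0, 30.1])
        with pytest.raises(ValueError):
            classify_propagation_pattern(ts, (29.0, 33.0), pos)
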