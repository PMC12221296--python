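"""Spike removal, downsampling, burst detection, phase and QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syncond import (
    DetectionError,
    ParameterError,
    PipelineConfig,
    Recording,
    compute_phase,
    detect_burst_onsets,
    downsample,
    qc_epoch,
    rectify_integrate,
    remove_spikes,
)
from syncond.core import ValidationError
from syncond.preprocess import CycleSet


class TestRemoveSpikes:
    def test_lone_outlier_rejected(self):
        vm = np.full(1000, -60.0)
        vm[500] = -20.0
        out = remove_spikes(vm, window=0.1, sample_rate=1000.0)
        np.testing.assert_allclose(out, -60.0)

    def test_slow_sinusoid_preserved(self):
        fs = 1000.0
        t = np.arange(5000) / fs
        vm = -60.0 + 5.0 * np.sin(2 * np.pi * 1.0 * t)
        out = remove_spikes(vm, window=0.1, sample_rate=fs)
        rms_err = np.sqrt(np.mean((out - vm) ** 2))
        rms_sig = np.sqrt(np.mean((vm - vm.mean()) ** 2))
        assert rms_err / rms_sig < 0.01

    def test_spikes_on_slow_wave(self):
        # threshold-reset style transients riding a slow wave
        fs = 2000.0
        t = np.arange(10000) / fs
        wave = -65.0 + 8.0 * np.sin(2 * np.pi * 0.5 * t)
        vm = wave.copy()
        rng = np.random.default_rng(0)
        for k in rng.integers(100, 9900, size=40):
            vm[k:k + 4] = 20.0  # 2 ms spikes
        out = remove_spikes(vm, window=0.1, sample_rate=fs)
        r = np.corrcoef(out, wave)[0, 1]
        assert r >= 0.99

    def test_idempotent_on_locally_monotone_input(self):
        # piecewise-monotone spike-free trace is a median-filter root
        fs = 1000.0
        up = np.linspace(-80, -50, 2000)
        vm = np.concatenate([up, up[::-1]])
        once = remove_spikes(vm, window=0.1, sample_rate=fs)
        twice = remove_spikes(once, window=0.1, sample_rate=fs)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_window_too_short(self):
        with pytest.raises(ParameterError):
            remove_spikes(np.zeros(100), window=0.01, sample_rate=100.0)


class TestDownsample:
    def test_constant_preserved(self):
        x = np.full(12500, 3.25)
        y = downsample(x, 12500.0, 100.0)
        assert y.size == 100
        np.testing.assert_allclose(y, 3.25)

    def test_sinusoid_matches_analytic(self):
        fs, to = 12500.0, 100.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = downsample(x, fs, to)
        tc = downsample(t, fs, to)  # block-center times
        # block averaging attenuates by sinc(f*T_block) ~ 1 - 1.6e-4
        assert np.max(np.abs(y - np.sin(2 * np.pi * tc))) < 1e-3

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ParameterError, match="integer"):
            downsample(np.zeros(12500), 12500.0, 300.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mean_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=1000)
        y = downsample(x, 1000.0, 100.0)
        assert y.mean() == pytest.approx(x.mean(), abs=1e-12)


class TestRectifyIntegrate:
    def test_zero_input(self):
        out = rectify_integrate(np.zeros(100), tau=0.05, sample_rate=100.0)
        np.testing.assert_allclose(out, 0.0)

    def test_step_response_time_constant(self):
        fs, tau = 1000.0, 0.05
        x = np.ones(1000)
        x[0] = 0.0
        y = rectify_integrate(x, tau=tau, sample_rate=fs)
        k = int(tau * fs)
        assert y[k] == pytest.approx(1 - np.exp(-1), abs=2.0 / (tau * fs))

    def test_burst_train_envelope_peaks_inside_bursts(self):
        fs = 1000.0
        t = np.arange(9000) / fs
        phase = (t / 3.0) % 1.0
        burst = (phase < 0.33).astype(float)
        rng = np.random.default_rng(1)
        x = burst * rng.normal(size=t.size)  # noisy nerve-like carrier
        y = rectify_integrate(x, tau=0.05, sample_rate=fs)
        for k in range(3):
            win = (t >= 3 * k) & (t < 3 * k + 3)
            t_peak = t[win][np.argmax(y[win])]
            assert (t_peak - 3 * k) / 3.0 < 0.4  # peak within the burst

    def test_tau_must_exceed_sample_interval(self):
        with pytest.raises(ParameterError):
            rectify_integrate(np.zeros(10), tau=0.001, sample_rate=100.0)


def _triangular_bursts(n_cycles=10, period=3.0, fs=200.0, jitter=0.0,
                       seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int((n_cycles + 0.5) * period * fs)) / fs
    onsets = 0.25 * period + period * np.arange(n_cycles)
    onsets = onsets + rng.normal(0.0, jitter, size=n_cycles)
    y = np.zeros_like(t)
    for on in onsets:
        m = (t >= on) & (t < on + 1.0)
        y[m] = np.interp(t[m] - on, [0.0, 0.5, 1.0], [0.0, 1.0, 0.0])
    return t, y, onsets


class TestDetectBurstOnsets:
    def test_noiseless_triangles(self):
        t, y, _ = _triangular_bursts()
        cyc = detect_burst_onsets(t, y, threshold_frac=0.10)
        assert cyc.n_cycles == 9
        np.testing.assert_allclose(cyc.periods, 3.0, atol=1e-6)
        assert cyc.cv_period == pytest.approx(0.0, abs=1e-6)

    def test_onset_at_ten_percent_crossing(self):
        t, y, onsets = _triangular_bursts()
        cyc = detect_burst_onsets(t, y, threshold_frac=0.10)
        # rising edge spans 0.5 s from 0 to 1, so 10% is crossed 0.05 s in
        np.testing.assert_allclose(cyc.onsets, onsets + 0.05,
                                   atol=1e-2)

    def test_jitter_reflected_in_cv(self):
        sd = 0.05
        t, y, _ = _triangular_bursts(n_cycles=200, jitter=sd, seed=4)
        cyc = detect_burst_onsets(t, y, threshold_frac=0.10)
        # independent onset jitter: period sd = sqrt(2)*sd
        expect = np.sqrt(2) * sd / 3.0
        assert cyc.cv_period == pytest.approx(expect, rel=0.25)

    def test_flat_signal_rejected(self):
        t = np.arange(1000) / 100.0
        with pytest.raises(DetectionError):
            detect_burst_onsets(t, np.ones_like(t))


class TestComputePhase:
    def test_reference_points(self):
        cyc = CycleSet(onsets=np.array([10.0, 13.0]),
                       periods=np.array([3.0]), cv_period=0.0,
                       inspiratory_fraction=0.33)
        phase, ok = compute_phase(np.array([10.0, 11.5]), cyc)
        assert phase[0] == 0.0
        assert phase[1] == pytest.approx(0.5)
        assert ok.all()

    def test_piecewise_cycles_and_exclusion(self):
        cyc = CycleSet(onsets=np.array([0.0, 2.0, 5.0]),
                       periods=np.array([2.0, 3.0]), cv_period=0.0,
                       inspiratory_fraction=0.33)
        t = np.array([-1.0, 3.5, 5.5])
        phase, ok = compute_phase(t, cyc)
        assert not ok[0] and np.isnan(phase[0])
        assert phase[1] == pytest.approx(0.5)   # second cycle midpoint
        assert not ok[2]                        # beyond last onset

    @given(st.lists(st.floats(0.5, 5.0), min_size=2, max_size=8),
           st.floats(0.0, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_monotone_within_cycle_and_zero_at_onsets(self, gaps, frac):
        onsets = np.concatenate([[0.0], np.cumsum(gaps)])
        cyc = CycleSet(onsets=onsets, periods=np.diff(onsets),
                       cv_period=0.0, inspiratory_fraction=0.33)
        phase_on, ok = compute_phase(onsets[:-1], cyc)
        np.testing.assert_allclose(phase_on, 0.0)
        # within an arbitrary cycle the phase is increasing
        k = len(gaps) // 2
        ts = onsets[k] + np.linspace(0, 0.999, 20) * cyc.periods[k]
        phase, ok = compute_phase(ts, cyc)
        assert ok.all()
        assert np.all(np.diff(phase) > 0)
        assert np.all((phase >= 0) & (phase < 1))


def _qc_recording(n_plateaus=4, cycles_per=6, period=3.0, fs=100.0,
                  drift_mv_per_min=0.0):
    n = int(n_plateaus * cycles_per * period * fs)
    t = np.arange(n) / fs
    i_inj = -50.0 - 50.0 * (t // (cycles_per * period))
    vm = -70.0 + drift_mv_per_min / 60.0 * t + 0.02 * i_inj
    phase = (t / period) % 1.0
    ref = np.where(phase < 0.33, 1.0, 0.0)
    return Recording(time=t, vm=vm, i_inj=i_inj, ref=ref, sample_rate=fs)


def _cycles_for(rec, period=3.0):
    n_on = int(rec.duration // period) + 1
    onsets = period * np.arange(n_on)
    return CycleSet(onsets=onsets, periods=np.diff(onsets),
                    cv_period=float(np.std(np.diff(onsets), ddof=1)
                                    / np.mean(np.diff(onsets))),
                    inspiratory_fraction=0.33)


class TestQC:
    def test_cv_criterion_sample_statistics(self):
        periods = np.array([3.0, 3.1, 2.9, 3.0, 3.0])
        cv = periods.std(ddof=1) / periods.mean()
        assert cv == pytest.approx(0.0236, abs=5e-4)
        assert cv < 0.10

    def test_two_plateaus_fail_min_steps(self, config):
        rec = _qc_recording(n_plateaus=2)
        report = qc_epoch(rec, _cycles_for(rec), config)
        assert not report.passed
        assert "min_steps" in report.reasons

    def test_good_epoch_passes(self, config):
        rec = _qc_recording(n_plateaus=4, cycles_per=6)
        report = qc_epoch(rec, _cycles_for(rec), config)
        assert report.passed
        assert report.n_steps == 4
        assert all(c >= 5 for c in report.cycles_per_step)

    def test_drift_flagged(self, config):
        rec = _qc_recording(drift_mv_per_min=3.0)
        report = qc_epoch(rec, _cycles_for(rec), config)
        assert report.drift_flag
        assert "drift" in report.reasons
        assert report.drift_slope == pytest.approx(3.0, rel=0.2)

    def test_high_cv_fails(self, config):
        rec = _qc_recording()
        cyc = _cycles_for(rec)
        bad = CycleSet(onsets=cyc.onsets, periods=cyc.periods,
                       cv_period=0.2, inspiratory_fraction=0.33)
        report = qc_epoch(rec, bad, config)
        assert "cv_period" in report.reasons
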