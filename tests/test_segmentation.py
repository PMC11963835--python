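"""Fast-/slow-phase separation, FPN frequency and bias velocity."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from povar import (EyeTrace, SegmentationConfig, StimulusProfile,
                   bias_velocity, fpn_frequency, generate_trace,
                   scenario_params, segment_phases, smooth_and_differentiate)
from povar.errors import (InvalidParameterError, InvalidWindowError,
                          UnreliableEstimateError)
from povar.segmentation import PhaseLabel


def make_trace(y, fs=60.0):
    n = len(y)
    return EyeTrace(timestamps=np.arange(n) / fs, horizontal=np.asarray(y, float),
                    vertical=np.zeros(n), sampling_rate=fs)


def match_events(detected_onsets, true_onsets, tol=0.05):
    used = set()
    matched = 0
    for o in true_onsets:
        for j, d in enumerate(detected_onsets):
            if j not in used and abs(d - o) <= tol:
                used.add(j)
                matched += 1
                break
    return matched


class TestSmoothAndDifferentiate:
    def test_linear_ramp_velocity(self):
        t = np.arange(600) / 60.0
        trace = make_trace(8.0 * t)
        vel, acc = smooth_and_differentiate(trace, cutoff=10.0)
        interior = slice(30, -30)
        assert np.allclose(vel[interior], 8.0, atol=0.01)
        assert np.allclose(acc[interior], 0.0, atol=1.0)

    def test_sinusoid_peak_velocity_matches_calculus(self):
        t = np.arange(3600) / 60.0
        a, f = 5.0, 0.5
        trace = make_trace(a * np.sin(2 * np.pi * f * t))
        vel, _ = smooth_and_differentiate(trace, cutoff=10.0)
        assert np.max(vel) == pytest.approx(2 * np.pi * f * a, rel=0.02)

    def test_filter_reduces_noise_velocity_variance(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.5, 3600)
        trace = make_trace(noise)
        vel_filtered, _ = smooth_and_differentiate(trace, cutoff=10.0)
        vel_raw = np.gradient(noise, 1 / 60.0)
        assert np.var(vel_filtered) < np.var(vel_raw)

    def test_cutoff_above_nyquist_rejected(self):
        trace = make_trace(np.zeros(100))
        with pytest.raises(InvalidParameterError):
            smooth_and_differentiate(trace, cutoff=30.0)


class TestSegmentPhases:
    def test_detects_every_injected_quick_phase(self):
        """60 s control trace, sparse 10-degree quick phases, 0.1 deg noise."""
        profile = StimulusProfile(paradigm="pOVAR", main_axis_velocity=336,
                                  eccentric_axis_velocity=72, duration=60)
        sc = scenario_params("control", seed=11, bias_velocity=0.0,
                             quick_phase_rate=0.5, orbital_limit=1e6,
                             quick_phase_amplitude_sd=0.0)
        trace, gt = generate_trace(profile, sc)
        seg = segment_phases(trace, analysis_window=(0.0, 60.0))
        assert len(seg.events) == gt.n_quick_phases
        detected = [e.onset for e in seg.events]
        for onset in gt.quick_phase_onsets:
            assert min(abs(d - onset) for d in detected) <= 0.025

    def test_pure_slow_sinusoid_yields_no_events(self):
        t = np.arange(3600) / 60.0
        seg = segment_phases(make_trace(5.0 * np.sin(2 * np.pi * 0.2 * t)),
                             analysis_window=(0, 60))
        assert seg.events == []

    def test_constant_trace_all_slow(self):
        seg = segment_phases(make_trace(np.full(1200, 3.0)), analysis_window=(0, 20))
        assert seg.events == []
        assert np.all(seg.labels == PhaseLabel.SLOW)

    def test_noiseless_events_match_injection_oracle(self):
        """Detected event set equals the injected-waveform oracle (noiseless)."""
        profile = StimulusProfile(paradigm="pOVAR", main_axis_velocity=336,
                                  eccentric_axis_velocity=72, duration=60)
        sc = scenario_params("control", seed=2, noise_sd=0.0, bias_velocity=0.0,
                             quick_phase_rate=0.4, orbital_limit=1e6)
        trace, gt = generate_trace(profile, sc)
        seg = segment_phases(trace, analysis_window=(0.0, 60.0))
        assert len(seg.events) == gt.n_quick_phases
        dt = 1.0 / trace.sampling_rate
        for event, onset in zip(seg.events, sorted(gt.quick_phase_onsets)):
            assert abs(event.onset - onset) <= 2 * dt

    def test_event_amplitude_sign_matches_direction(self, povar_profile):
        trace, _ = generate_trace(povar_profile, scenario_params("control", seed=3))
        seg = segment_phases(trace)
        for e in seg.events:
            assert (e.direction == "positive") == (e.amplitude >= 0)

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidWindowError):
            segment_phases(make_trace(np.zeros(600)), analysis_window=(5.0, 5.0))


class TestMetrics:
    def test_fpn_frequency_is_event_count_over_window(self, povar_profile):
        trace, _ = generate_trace(povar_profile, scenario_params("control", seed=4))
        seg = segment_phases(trace)
        m = fpn_frequency(seg)
        assert m.fpn_frequency * m.window_duration == pytest.approx(m.n_quick_phases)

    def test_canal_null_scenario_has_no_fast_phases(self, povar_profile):
        trace, _ = generate_trace(povar_profile, scenario_params("canal_null", seed=5))
        seg = segment_phases(trace)
        m = fpn_frequency(seg)
        assert m.n_quick_phases == 0 and m.fpn_frequency == 0.0

    def test_bias_recovered_within_five_percent(self, povar_profile):
        sc = scenario_params("control", seed=6, bias_velocity=-8.0,
                             smc_amplitude_h=3.0)
        trace, gt = generate_trace(povar_profile, sc)
        seg = segment_phases(trace)
        bias = bias_velocity(trace, seg, povar_profile.modulation_frequency_hz)
        assert bias == pytest.approx(-8.0, rel=0.05)

    def test_static_trace_zero_bias(self):
        seg = segment_phases(make_trace(np.zeros(7200)), analysis_window=(0, 120))
        trace = make_trace(np.zeros(7200))
        assert bias_velocity(trace, seg, 0.2) == pytest.approx(0.0, abs=1e-9)

    def test_cw_stimulation_gives_negative_bias(self, povar_profile):
        """Compensatory slow phase opposes CW rotation, so the bias is negative."""
        assert povar_profile.direction == 1
        trace, gt = generate_trace(povar_profile, scenario_params("control", seed=7))
        seg = segment_phases(trace)
        assert gt.true_bias_velocity < 0
        assert bias_velocity(trace, seg, povar_profile.modulation_frequency_hz) < 0

    def test_bias_and_fpn_covary_across_rate_sweep(self):
        """Steady-state |bias| and FPN rate rank together (Spearman > 0.9)."""
        profile = StimulusProfile(paradigm="pOVAR", main_axis_velocity=336,
                                  eccentric_axis_velocity=108, duration=120)
        biases, rates = [], []
        for i, b in enumerate(np.linspace(2, 14, 10)):
            sc = scenario_params("control", seed=20 + i, bias_velocity=-b,
                                 quick_phase_rate=0.1 * b)
            trace, _ = generate_trace(profile, sc)
            seg = segment_phases(trace)
            rates.append(fpn_frequency(seg).fpn_frequency)
            biases.append(abs(bias_velocity(trace, seg, profile.modulation_frequency_hz)))
        rho, _ = stats.spearmanr(biases, rates)
        assert rho > 0.9

    def test_mostly_fast_window_flagged_unreliable(self):
        t = np.arange(7200) / 60.0
        rng = np.random.default_rng(1)
        # dense large saccades leave too little slow data
        y = np.cumsum(rng.choice([-12.0, 12.0], size=7200))
        trace = make_trace(y)
        seg = segment_phases(trace, analysis_window=(0, 120))
        if (seg.labels == PhaseLabel.SLOW).sum() < 0.5 * len(t):
            with pytest.raises(UnreliableEstimateError):
                bias_velocity(trace, seg, 0.2)
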