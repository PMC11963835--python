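"""Synthetic-data generator: determinism, ground-truth fidelity, scenarios."""

import dataclasses

import numpy as np
import pytest

from povar import (StimulusProfile, generate_frames, generate_tav_trace,
                   generate_trace, scenario_params)
from povar.errors import (InsufficientDataError, InvalidParameterError,
                          InvalidTrajectoryError)
from povar.synth import ScenarioParams


class TestGenerateTrace:
    def test_same_seed_is_bit_identical(self, povar_profile):
        sc = scenario_params("control", seed=42)
        tr1, gt1 = generate_trace(povar_profile, sc)
        tr2, gt2 = generate_trace(povar_profile, sc)
        assert np.array_equal(tr1.horizontal, tr2.horizontal)
        assert np.array_equal(tr1.vertical, tr2.vertical)
        assert np.array_equal(gt1.quick_phase_onsets, gt2.quick_phase_onsets)

    def test_clean_scenario_is_exact_sinusoid(self, povar_profile):
        sc = scenario_params("control", noise_sd=0.0, quick_phase_rate=0.0,
                             bias_velocity=0.0)
        tr, gt = generate_trace(povar_profile, sc)
        t = tr.timestamps
        f = povar_profile.modulation_frequency_hz
        expected = sc.smc_amplitude_h * np.sin(2 * np.pi * f * t)
        assert np.max(np.abs(tr.horizontal - expected)) < 1e-9
        assert gt.n_quick_phases == 0

    def test_ground_truth_onsets_strictly_increasing_and_separated(self, povar_profile):
        _, gt = generate_trace(povar_profile, scenario_params("control", seed=5))
        gaps = np.diff(gt.quick_phase_onsets)
        assert np.all(gaps > gt.quick_phase_duration)

    def test_removing_quick_phases_recovers_bias_and_smc(self, povar_profile):
        """Subtracting the injected half-cosine steps leaves line + sinusoid."""
        sc = scenario_params("control", seed=7, noise_sd=0.0)
        tr, gt = generate_trace(povar_profile, sc)
        t = tr.timestamps
        resid = tr.horizontal.copy()
        for onset, amp in zip(gt.quick_phase_onsets, gt.quick_phase_amplitudes):
            rel = t - onset
            d = gt.quick_phase_duration
            wave = np.where(rel >= d, amp,
                            0.5 * amp * (1 - np.cos(np.pi * np.clip(rel, 0, d) / d)))
            resid -= np.where(rel < 0, 0.0, wave)
        f = povar_profile.modulation_frequency_hz
        design = np.column_stack([np.ones_like(t), t,
                                  np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
        coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
        assert coef[1] == pytest.approx(gt.true_bias_velocity, rel=0.01)
        assert np.hypot(coef[2], coef[3]) == pytest.approx(gt.true_smc_amplitude_h, rel=0.01)

    def test_poisson_event_count_matches_rate(self, povar_profile):
        """Counts over 50 seeds stay within 3 SD of the commanded Poisson rate."""
        sc_base = dict(scenario="custom", bias_velocity=0.0, quick_phase_rate=0.5,
                       orbital_limit=60.0, noise_sd=0.0)
        counts = [generate_trace(povar_profile, ScenarioParams(**sc_base, seed=s))[1].n_quick_phases
                  for s in range(50)]
        expected = 0.5 * povar_profile.duration
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected) / np.sqrt(50)

    def test_uvl_left_suppresses_ccw_event_rate(self, povar_profile, povar_profile_ccw):
        ratios = []
        for seed in range(20):
            _, gt_cw = generate_trace(povar_profile, scenario_params("uvl_left", seed=seed))
            _, gt_ccw = generate_trace(povar_profile_ccw,
                                       scenario_params("uvl_left", seed=seed + 500))
            ratios.append(gt_ccw.n_quick_phases / gt_cw.n_quick_phases)
        assert 0.5 <= np.mean(ratios) <= 0.7

    def test_lesion_scenarios_zero_the_right_components(self):
        canal = scenario_params("canal_null")
        assert canal.bias_velocity == 0 and canal.quick_phase_rate == 0
        assert canal.smc_amplitude_v > 0
        otolith = scenario_params("otolith_null")
        assert otolith.smc_amplitude_v == 0 and otolith.smc_amplitude_h == 0
        assert otolith.bias_velocity == 0

    def test_too_short_recording_rejected(self):
        short = StimulusProfile(paradigm="pOVAR", main_axis_velocity=336,
                                eccentric_axis_velocity=72, duration=20)
        with pytest.raises(InsufficientDataError):
            generate_trace(short, scenario_params("control"))


class TestGenerateTavTrace:
    def test_envelope_definition_of_tau(self, tav_profile):
        sc = scenario_params("control", noise_sd=0.0, quick_phase_rate=0.0,
                             orbital_limit=1e6)
        tr, gt = generate_tav_trace(tav_profile, tau=5.0, scenario=sc, step_time=5.0)
        t = tr.timestamps
        dt = 1.0 / tr.sampling_rate
        vel = np.gradient(tr.horizontal, dt)
        v0 = vel[np.argmin(np.abs(t - 5.0)) + 1]
        v_at_tau = vel[np.argmin(np.abs(t - 10.0))]
        assert v_at_tau == pytest.approx(v0 / np.e, rel=0.02)
        assert gt.true_time_constant == 5.0

    def test_short_vs_long_tau_envelopes_diverge(self, tav_profile):
        sc = scenario_params("control", noise_sd=0.0, quick_phase_rate=0.0,
                             orbital_limit=1e6)
        t_eval = 4.0
        envelopes = []
        for tau in (1.0, 5.0):
            tr, _ = generate_tav_trace(tav_profile, tau=tau, scenario=sc, step_time=0.0)
            vel = np.gradient(tr.horizontal, 1.0 / tr.sampling_rate)
            envelopes.append(abs(vel[np.argmin(np.abs(tr.timestamps - t_eval))]))
        assert envelopes[1] > 3 * envelopes[0]

    def test_invalid_tau_rejected(self, tav_profile, control_scenario):
        with pytest.raises(InvalidParameterError):
            generate_tav_trace(tav_profile, tau=-1.0, scenario=control_scenario)

    def test_requires_tav_paradigm(self, povar_profile, control_scenario):
        with pytest.raises(InvalidParameterError):
            generate_tav_trace(povar_profile, tau=5.0, scenario=control_scenario)


class TestGenerateFrames:
    def test_single_frame_truth_passthrough(self):
        frames, centers = generate_frames([(120.0, 80.0)])
        assert frames.shape == (1, 160, 240)
        assert tuple(centers[0]) == (120.0, 80.0)

    def test_empty_trajectory_gives_empty_stack(self):
        frames, centers = generate_frames([])
        assert frames.shape[0] == 0 and len(centers) == 0

    def test_pupil_darker_than_iris(self):
        frames, _ = generate_frames([(120, 80)])
        assert frames[0, 80, 120] < 0.2 < 0.5 < frames[0, 5, 5]

    def test_out_of_bounds_trajectory_rejected(self):
        with pytest.raises(InvalidTrajectoryError):
            generate_frames([(5.0, 5.0)])

    def test_noise_is_seed_deterministic(self):
        f1, _ = generate_frames([(120, 80)], noise_sd=0.05, seed=3)
        f2, _ = generate_frames([(120, 80)], noise_sd=0.05, seed=3)
        assert np.array_equal(f1, f2)
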