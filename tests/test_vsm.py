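"""Velocity-storage internal model: equilibria, lesion phenotypes, round trip."""

import dataclasses

import numpy as np
import pytest

from povar import StimulusProfile, VSMParams, VSMState, simulate, step, vsm_scenario
from povar.errors import InvalidParameterError
from povar.segmentation import fpn_frequency, segment_phases
from povar.modulation import fit_smc
from povar.timeconstant import fit_time_constant, slow_phase_envelope

GRAVITY = 9.80665


def povar_profile(direction=1, v_main=336, v_ecc=108, duration=100):
    return StimulusProfile(paradigm="pOVAR", main_axis_velocity=v_main,
                           eccentric_axis_velocity=direction * v_ecc,
                           duration=duration)


def run(profile, params=VSMParams(), duration=100.0, window=(80.0, 100.0)):
    return simulate(profile, params, duration=duration, steady_window=window)


class TestStep:
    def test_rest_is_a_fixed_point(self):
        state = VSMState.initial()
        gia = np.array([0.0, 0.0, GRAVITY])
        omega = np.zeros(3)
        for _ in range(200):
            state = step(state, VSMParams(), gia, omega, dt=0.001)
        assert np.allclose(state.omega_est, 0.0, atol=1e-12)
        assert np.allclose(state.g_est, gia, atol=1e-9)
        assert state.eye_position == pytest.approx(0.0, abs=1e-12)
        assert state.eye_velocity == pytest.approx(0.0, abs=1e-12)

    def test_step_matches_simulate_trajectory(self):
        """Single-step API and the compiled batch integrator agree."""
        profile = povar_profile(duration=2)
        res = simulate(profile, duration=2.0, steady_window=(0.0, 2.0))
        from povar.stimulus import gia_array
        _, gia = gia_array(profile, 1000.0)
        omega = np.array([0.0, 0.0, -profile.eccentric_axis_velocity])
        state = VSMState.initial()
        n = 150  # stay ahead of the first orbital reset (simulate-only behaviour)
        for i in range(n):
            state = step(state, VSMParams(), gia[i], omega, dt=0.001)
        assert state.eye_position == pytest.approx(res.eye_position[n], abs=1e-6)
        assert np.allclose(state.g_est, res.g_est[n], atol=1e-9)


class TestScenarios:
    def test_scenario_parameter_edits(self):
        base = VSMParams()
        assert vsm_scenario("canal_null", base).canal_gain_left == 0.0
        assert vsm_scenario("canal_null", base).canal_gain_right == 0.0
        assert vsm_scenario("otolith_null", base).otolith_gain == 0.0
        assert vsm_scenario("uvl_left", base).canal_gain_left == pytest.approx(0.2)
        st = vsm_scenario("storage_attenuated", base)
        assert st.storage_time_constant == pytest.approx(base.storage_time_constant * 0.5)
        with pytest.raises(ValueError):
            vsm_scenario("unknown")

    def test_canal_loss_silences_fast_phases_but_keeps_smc(self):
        """Canal-null steady state: no rotation estimate, SMC intact."""
        prof = povar_profile()
        control = run(prof)
        lesioned = run(prof, vsm_scenario("canal_null"))
        ctrl_yaw = np.abs(control.omega_est_cw[80000:]).mean()
        les_yaw = np.abs(lesioned.omega_est_cw[80000:]).mean()
        assert les_yaw < 0.01 * ctrl_yaw
        assert lesioned.metrics.fpn_frequency == 0.0
        # otolith-driven modulation survives
        seg = segment_phases(lesioned.to_trace(), analysis_window=(80, 100))
        fit = fit_smc(lesioned.to_trace(), seg, prof.modulation_frequency_hz)
        assert fit.amplitude > 0.5

    def test_otolith_loss_stills_the_eye_at_steady_state(self):
        lesioned = run(povar_profile(), vsm_scenario("otolith_null"))
        steady_speed = np.abs(lesioned.eye_velocity[80000:]).mean()
        assert steady_speed < 0.2  # deg/s, after the canal transient decays

    def test_storage_attenuation_cuts_fpn_but_not_smc(self):
        prof = povar_profile()
        control = run(prof)
        att = run(prof, vsm_scenario("storage_attenuated"))
        assert att.metrics.fpn_frequency < control.metrics.fpn_frequency
        f = prof.modulation_frequency_hz
        amp_c = fit_smc(control.to_trace(),
                        segment_phases(control.to_trace(), analysis_window=(80, 100)), f).amplitude
        amp_a = fit_smc(att.to_trace(),
                        segment_phases(att.to_trace(), analysis_window=(80, 100)), f).amplitude
        assert abs(amp_a - amp_c) / amp_c < 0.10

    def test_unilateral_lesions_bias_the_expected_direction(self):
        for name, suppressed in (("uvl_left", -1), ("uvl_right", +1)):
            params = vsm_scenario(name)
            f_sup = run(povar_profile(direction=suppressed), params).metrics.fpn_frequency
            f_int = run(povar_profile(direction=-suppressed), params).metrics.fpn_frequency
            assert f_sup < f_int
            assert f_sup / f_int < 1.0


class TestSimulateDynamics:
    def test_steady_bias_opposes_head_rotation(self):
        cw = run(povar_profile(direction=1))
        ccw = run(povar_profile(direction=-1))
        assert cw.metrics.bias_velocity < 0 < ccw.metrics.bias_velocity

    def test_direction_reversal_mirrors_the_trajectory(self):
        cw = run(povar_profile(direction=1))
        ccw = run(povar_profile(direction=-1))
        assert np.allclose(cw.eye_position, -ccw.eye_position, atol=1e-6)
        assert np.allclose(cw.omega_est_cw, -ccw.omega_est_cw, atol=1e-6)

    def test_bias_magnitude_monotone_in_tilt(self):
        biases = []
        for v in (186, 336):
            prof = povar_profile(v_main=v, v_ecc=72)
            biases.append(abs(run(prof).metrics.bias_velocity))
        assert biases[0] < biases[1]

    def test_states_bounded_over_long_run(self):
        res = simulate(povar_profile(duration=150), duration=150.0)
        assert np.all(np.abs(res.eye_position) <= VSMParams().quick_phase_orbital_limit + 1.0)
        assert np.all(np.abs(res.omega_est_cw) < 200.0)
        gnorm = np.linalg.norm(res.g_est, axis=1)
        assert np.all((gnorm > 0.5 * GRAVITY) & (gnorm < 1.5 * GRAVITY))

    def test_pipeline_fpn_matches_event_log(self):
        """Round trip: segmentation on the simulated trace vs the reset log."""
        res = run(povar_profile(), window=(60.0, 100.0))
        seg = segment_phases(res.to_trace(), analysis_window=(60.0, 100.0))
        pipeline_fpn = fpn_frequency(seg).fpn_frequency
        assert pipeline_fpn == pytest.approx(res.metrics.fpn_frequency, rel=0.05)

    def test_storage_prolongs_post_step_decay(self):
        prof = StimulusProfile(paradigm="TAV", duration=60, tav_plateau_velocity=100,
                               eccentric_axis_velocity=0)
        intact = simulate(prof, duration=60.0, tav_stop_time=20.0)
        canal_only = simulate(prof, dataclasses.replace(VSMParams(), storage_coupling=0.0,
                                                        k_F=0.0),
                              duration=60.0, tav_stop_time=20.0)
        taus = []
        for res in (intact, canal_only):
            trace = res.to_trace()
            seg = segment_phases(trace, analysis_window=(0.0, 60.0))
            env = slow_phase_envelope(trace, seg, step_time=21.0)
            taus.append(fit_time_constant(env).tau)
        assert taus[0] > taus[1]
        assert taus[0] > VSMParams().canal_time_constant

    def test_too_coarse_dt_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate(povar_profile(), dt=1.0)
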