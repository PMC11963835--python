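"""Velocity-storage internal-model simulator.

An executable formalization of the canal-otolith circuit believed to
generate OVAR nystagmus: semicircular canals high-pass the head angular
velocity; the otoliths report the gravito-inertial acceleration (GIA); a
central estimator maintains an internal gravity vector (tilt estimator) and
an internal angular-velocity estimate held in a leaky storage integrator.
The rotating GIA of OVAR, compared against the lagging internal gravity
estimate, yields a rotation-feedback drive ``k_F * (GIA x G_hat)`` that
recharges the storage and so converts a purely oscillatory otolith signal
into a sustained bias — but only when canal input participates: the per-side
canal gains gate both the canal signal and the rotation feedback, so canal
loss silences the bias (and with it the fast-phase nystagmus) while leaving
the otolith-driven sinusoidal modulation untouched, and a unilateral lesion
suppresses the bias of one rotation direction only.

Concrete dynamics (head frame, x naso-occipital +nose, y interaural +left,
z dorso-ventral +up; right-handed, so CW-viewed-from-above is negative
omega_z; public inputs/outputs use the CW-positive scalar convention):

    canal      x' = (Omega - x) / tau_c          V_scc = Omega - x
    gravity    g_hat' = -omega_est x g_hat
                        + k_g * s_oto * (g * GIA/|GIA| - g_hat)
    storage    s' = -s / tau_s + k_sc * C + gate(f) * k_F * s_oto * f,
               C = gate(V_scc) * V_scc,  f = GIA x g_hat
    estimate   omega_est = C + s
    eye        v_eye = -G_vor * omega_est_cw + k_smc * s_oto * GIA_y
               e' = v_eye, reset toward center when |e| > orbital limit

``gate(v)`` scales a vector by the right canal gain when its yaw component
is CW and by the left gain when CCW (each canal is excited by rotation
toward its own side).  Quick phases are deterministic orbital resets, so the
simulated fast-phase rate is a reproducible function of the bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from numba import njit

from .errors import (InvalidParameterError, SimulationUnstableError,
                     UnsupportedParadigmError)
from .segmentation import NystagmusMetrics
from .stimulus import Paradigm, StimulusProfile
from .synth import Scenario
from .trace import EyeTrace

DEG2RAD = np.pi / 180.0


@dataclass(frozen=True)
class VSMParams:
    canal_time_constant: float = 4.0     # s, canal high-pass
    storage_time_constant: float = 15.0  # s, leaky storage integrator
    k_F: float = 0.04                    # (deg/s)/(m^2/s^4), rotation feedback
    canal_gain_left: float = 1.0
    canal_gain_right: float = 1.0
    otolith_gain: float = 1.0
    vor_gain: float = 0.8
    quick_phase_orbital_limit: float = 15.0   # deg
    quick_phase_reset_fraction: float = 0.9
    quick_phase_duration: float = 0.040  # s, half-cosine reset profile
    tilt_correction_gain: float = 2.0    # 1/s, g_hat pull toward GIA direction
    storage_coupling: float = 0.07       # 1/s; ~unit DC gain with the default leak
    otolith_smc_gain: float = 0.5        # (deg/s)/(m/s^2), horizontal SMC drive

    def __post_init__(self) -> None:
        if self.canal_time_constant <= 0 or self.storage_time_constant <= 0:
            raise InvalidParameterError("time constants must be > 0")
        if self.storage_time_constant <= self.canal_time_constant:
            raise InvalidParameterError("storage_time_constant must exceed canal_time_constant")
        for name in ("canal_gain_left", "canal_gain_right", "otolith_gain"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if not 0.0 < self.quick_phase_reset_fraction <= 1.0:
            raise InvalidParameterError("quick_phase_reset_fraction must be in (0, 1]")
        if self.quick_phase_orbital_limit <= 0:
            raise InvalidParameterError("quick_phase_orbital_limit must be > 0")


@dataclass
class VSMState:
    omega_head: np.ndarray    # deg/s, true head angular velocity (internal frame)
    canal_signal: np.ndarray  # deg/s, V_scc
    gia: np.ndarray           # m/s^2
    g_est: np.ndarray         # m/s^2, internal gravity estimate
    omega_est: np.ndarray     # deg/s, internal angular-velocity estimate
    eye_position: float       # deg, CW-positive scalar
    eye_velocity: float       # deg/s
    canal_lp: np.ndarray = None  # internal low-pass state x (Omega - V_scc)

    @classmethod
    def initial(cls, gravity: float = 9.80665) -> "VSMState":
        z = np.zeros(3)
        return cls(omega_head=z.copy(), canal_signal=z.copy(),
                   gia=np.array([0.0, 0.0, gravity]),
                   g_est=np.array([0.0, 0.0, gravity]),
                   omega_est=z.copy(), eye_position=0.0, eye_velocity=0.0,
                   canal_lp=z.copy())


def _gate(vec: np.ndarray, params: VSMParams) -> np.ndarray:
    """Per-side canal gain on a yaw signal.

    Internal-frame positive z is CCW (leftward), handled by the left canal;
    negative z (CW) by the right.  Zero yaw uses the mean gain.
    """
    if vec[2] > 0:
        g = params.canal_gain_left
    elif vec[2] < 0:
        g = params.canal_gain_right
    else:
        g = 0.5 * (params.canal_gain_left + params.canal_gain_right)
    return g * vec


def _derivatives(y: np.ndarray, omega: np.ndarray, gia: np.ndarray,
                 params: VSMParams, gravity: float) -> tuple[np.ndarray, np.ndarray, float]:
    """RHS of the model ODEs.

    ``y`` packs [canal_lp (3), g_est (3), storage (3), eye_position (1)].
    Returns (dy/dt, omega_est, eye_velocity).
    """
    x, g_hat, s = y[0:3], y[3:6], y[6:9]
    v_scc = omega - x
    c = _gate(v_scc, params)
    omega_est = c + s

    dx = (omega - x) / params.canal_time_constant

    gia_norm = np.linalg.norm(gia)
    target = gravity * gia / gia_norm if gia_norm > 0 else g_hat
    dg = (-np.cross(omega_est * DEG2RAD, g_hat)
          + params.tilt_correction_gain * params.otolith_gain * (target - g_hat))

    feedback = np.cross(gia, g_hat)
    ds = (-s / params.storage_time_constant
          + params.storage_coupling * c
          + params.k_F * params.otolith_gain * _gate(feedback, params))

    omega_est_cw = -omega_est[2]  # internal z (CCW+) -> public CW-positive scalar
    eye_velocity = (-params.vor_gain * omega_est_cw
                    + params.otolith_smc_gain * params.otolith_gain * gia[1])
    dy = np.empty(10)
    dy[0:3], dy[3:6], dy[6:9], dy[9] = dx, dg, ds, eye_velocity
    return dy, omega_est, eye_velocity


def step(state: VSMState, params: VSMParams, gia_sample: np.ndarray,
         omega_sample: np.ndarray, dt: float, gravity: float = 9.80665) -> VSMState:
    """One RK4 integration step; returns the updated state.

    ``omega_sample`` is the true head angular velocity (deg/s, internal
    frame) and ``gia_sample`` the head-frame GIA (m/s^2), both held constant
    over the step.  Quick-phase resets are handled by the caller
    (:func:`simulate`) so that ``step`` itself stays smooth.
    """
    # storage vector = omega_est minus the gated canal contribution
    storage = np.asarray(state.omega_est) - _gate(np.asarray(state.canal_signal), params)
    y = np.concatenate([state.canal_lp, state.g_est, storage, [state.eye_position]])
    omega = np.asarray(omega_sample, dtype=float)
    gia = np.asarray(gia_sample, dtype=float)
    k1, _, _ = _derivatives(y, omega, gia, params, gravity)
    k2, _, _ = _derivatives(y + 0.5 * dt * k1, omega, gia, params, gravity)
    k3, _, _ = _derivatives(y + 0.5 * dt * k2, omega, gia, params, gravity)
    k4, _, _ = _derivatives(y + dt * k3, omega, gia, params, gravity)
    y_new = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(y_new)):
        names = ["canal_lp", "g_est", "storage", "eye_position"]
        first_bad = int(np.flatnonzero(~np.isfinite(y_new))[0])
        raise SimulationUnstableError(f"non-finite state in {names[min(first_bad // 3, 3)]}")
    _, omega_est, eye_vel = _derivatives(y_new, omega, gia, params, gravity)
    v_scc = omega - y_new[0:3]
    return VSMState(omega_head=omega, canal_signal=v_scc, gia=gia,
                    g_est=y_new[3:6], omega_est=omega_est,
                    eye_position=float(y_new[9]), eye_velocity=float(eye_vel),
                    canal_lp=y_new[0:3])


@njit(cache=False)
def _rhs(x0, x1, x2, g0, g1, g2, s0, s1, s2,
         om0, om1, om2, gia0, gia1, gia2,
         tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc, gravity):
    """Unrolled model RHS; returns 10 state derivatives + eye velocity."""
    # canal high-pass: V_scc = Omega - x, x a low-pass of Omega
    v0, v1, v2 = om0 - x0, om1 - x1, om2 - x2
    if v2 > 0.0:
        cg = gl
    elif v2 < 0.0:
        cg = gr
    else:
        cg = 0.5 * (gl + gr)
    c0, c1, c2 = cg * v0, cg * v1, cg * v2
    oe0, oe1, oe2 = c0 + s0, c1 + s1, c2 + s2
    dx0, dx1, dx2 = v0 / tc, v1 / tc, v2 / tc
    # gravity estimate: rotate with -omega_est, correct toward GIA direction
    w0, w1, w2 = oe0 * DEG2RAD, oe1 * DEG2RAD, oe2 * DEG2RAD
    cr0 = w1 * g2 - w2 * g1
    cr1 = w2 * g0 - w0 * g2
    cr2 = w0 * g1 - w1 * g0
    gn = (gia0 * gia0 + gia1 * gia1 + gia2 * gia2) ** 0.5
    if gn > 0.0:
        sc = gravity / gn
        t0, t1, t2 = gia0 * sc, gia1 * sc, gia2 * sc
    else:
        t0, t1, t2 = g0, g1, g2
    kgo = kg * so
    dg0 = -cr0 + kgo * (t0 - g0)
    dg1 = -cr1 + kgo * (t1 - g1)
    dg2 = -cr2 + kgo * (t2 - g2)
    # storage: leak + canal charge + gated rotation feedback k_F (GIA x g_hat)
    f0 = gia1 * g2 - gia2 * g1
    f1 = gia2 * g0 - gia0 * g2
    f2 = gia0 * g1 - gia1 * g0
    if f2 > 0.0:
        fg = gl
    elif f2 < 0.0:
        fg = gr
    else:
        fg = 0.5 * (gl + gr)
    kfe = kF * so * fg
    ds0 = -s0 / ts + ksc * c0 + kfe * f0
    ds1 = -s1 / ts + ksc * c1 + kfe * f1
    ds2 = -s2 / ts + ksc * c2 + kfe * f2
    eye_vel = -vor * (-oe2) + ksmc * so * gia1
    return dx0, dx1, dx2, dg0, dg1, dg2, ds0, ds1, ds2, eye_vel


@njit(cache=False)
def _simulate_core(omega, gia, dt, gravity, limit, reset_frac, qp_weights,
                   tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc):
    n = omega.shape[0]
    eye_pos = np.empty(n)
    eye_vel = np.empty(n)
    om_cw = np.empty(n)
    g_est = np.empty((n, 3))
    qp_t = np.empty(n)
    qp_a = np.empty(n)
    n_qp = 0
    qp_left = 0
    qp_total = 0.0
    x0 = x1 = x2 = 0.0
    g0, g1, g2 = 0.0, 0.0, gravity
    s0 = s1 = s2 = 0.0
    ep = 0.0
    lo_band = 0.4 * gravity
    hi_band = 1.6 * gravity
    for i in range(n):
        om0, om1, om2 = omega[i, 0], omega[i, 1], omega[i, 2]
        a0, a1, a2 = gia[i, 0], gia[i, 1], gia[i, 2]
        k1 = _rhs(x0, x1, x2, g0, g1, g2, s0, s1, s2, om0, om1, om2,
                  a0, a1, a2, tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc, gravity)
        h = 0.5 * dt
        k2 = _rhs(x0 + h * k1[0], x1 + h * k1[1], x2 + h * k1[2],
                  g0 + h * k1[3], g1 + h * k1[4], g2 + h * k1[5],
                  s0 + h * k1[6], s1 + h * k1[7], s2 + h * k1[8],
                  om0, om1, om2, a0, a1, a2,
                  tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc, gravity)
        k3 = _rhs(x0 + h * k2[0], x1 + h * k2[1], x2 + h * k2[2],
                  g0 + h * k2[3], g1 + h * k2[4], g2 + h * k2[5],
                  s0 + h * k2[6], s1 + h * k2[7], s2 + h * k2[8],
                  om0, om1, om2, a0, a1, a2,
                  tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc, gravity)
        k4 = _rhs(x0 + dt * k3[0], x1 + dt * k3[1], x2 + dt * k3[2],
                  g0 + dt * k3[3], g1 + dt * k3[4], g2 + dt * k3[5],
                  s0 + dt * k3[6], s1 + dt * k3[7], s2 + dt * k3[8],
                  om0, om1, om2, a0, a1, a2,
                  tc, ts, kF, gl, gr, so, vor, kg, ksc, ksmc, gravity)
        # record pre-step state; velocity from the k1 evaluation
        eye_pos[i] = ep
        eye_vel[i] = k1[9]
        v2 = om2 - x2
        cg = gl if v2 > 0.0 else (gr if v2 < 0.0 else 0.5 * (gl + gr))
        om_cw[i] = -(cg * v2 + s2)
        g_est[i, 0], g_est[i, 1], g_est[i, 2] = g0, g1, g2
        w = dt / 6.0
        x0 += w * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x1 += w * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        x2 += w * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        g0 += w * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        g1 += w * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        g2 += w * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
        s0 += w * (k1[6] + 2 * k2[6] + 2 * k3[6] + k4[6])
        s1 += w * (k1[7] + 2 * k2[7] + 2 * k3[7] + k4[7])
        s2 += w * (k1[8] + 2 * k2[8] + 2 * k3[8] + k4[8])
        ep += w * (k1[9] + 2 * k2[9] + 2 * k3[9] + k4[9])
        # quick-phase reset: spread over a half-cosine displacement profile so
        # the simulated trace is analyzable like a recorded one
        if qp_left > 0:
            ep += qp_total * qp_weights[len(qp_weights) - qp_left]
            qp_left -= 1
        elif abs(ep) > limit:
            qp_total = -reset_frac * ep
            qp_t[n_qp] = (i + 1) * dt
            qp_a[n_qp] = qp_total
            n_qp += 1
            qp_left = len(qp_weights)
        gnorm = (g0 * g0 + g1 * g1 + g2 * g2) ** 0.5
        if not (np.isfinite(ep) and lo_band < gnorm < hi_band):
            return eye_pos, eye_vel, om_cw, g_est, qp_t, qp_a, n_qp, 1
    return eye_pos, eye_vel, om_cw, g_est, qp_t, qp_a, n_qp, 0


@dataclass
class SimulationResult:
    times: np.ndarray
    eye_position: np.ndarray   # deg, CW-positive
    eye_velocity: np.ndarray   # deg/s (slow-phase command; resets are position jumps)
    omega_est_cw: np.ndarray   # deg/s, CW-positive yaw estimate
    g_est: np.ndarray          # (n, 3) m/s^2
    quick_phase_times: np.ndarray
    quick_phase_amplitudes: np.ndarray
    metrics: NystagmusMetrics
    steady_window: tuple[float, float]

    def to_trace(self) -> EyeTrace:
        fs = 1.0 / float(self.times[1] - self.times[0])
        return EyeTrace(timestamps=self.times, horizontal=self.eye_position,
                        vertical=np.zeros_like(self.eye_position), sampling_rate=fs)


def _omega_profile(profile: StimulusProfile, t: np.ndarray,
                   tav_stop_time: Optional[float]) -> np.ndarray:
    """True head yaw velocity (deg/s, internal CCW-positive z) over time."""
    omega = np.zeros((len(t), 3))
    if profile.paradigm in (Paradigm.POVAR, Paradigm.OVAR):
        # constant-velocity rotation from t=0; canal transient decays away
        omega[:, 2] = -profile.eccentric_axis_velocity  # CW-positive -> internal z
    elif profile.paradigm is Paradigm.TAV:
        stop = tav_stop_time if tav_stop_time is not None else profile.duration / 3.0
        plateau = profile.tav_plateau_velocity
        ramp = max(profile.tav_ramp, 1e-6)
        rise = np.clip(t * ramp, 0, abs(plateau)) * np.sign(plateau)
        fall = np.clip((t - stop) * ramp, 0, abs(plateau)) * np.sign(plateau)
        omega[:, 2] = -(rise - fall)
    else:
        raise UnsupportedParadigmError(f"simulate does not handle {profile.paradigm.value}")
    return omega


def simulate(profile: StimulusProfile, params: VSMParams = VSMParams(),
             duration: Optional[float] = None, dt: float = 0.001,
             tav_stop_time: Optional[float] = None,
             steady_window: Optional[tuple[float, float]] = None) -> SimulationResult:
    """Integrate the model over a stimulus profile.

    Returns the state trajectory, the quick-phase (orbital reset) event log,
    and fast-phase/bias metrics computed over ``steady_window`` (defaulting
    to the second half of the run).
    """
    duration = duration if duration is not None else profile.duration
    f = profile.modulation_frequency_hz
    if profile.paradigm in (Paradigm.POVAR, Paradigm.OVAR) and f > 0 and dt > 1.0 / (20.0 * f):
        raise InvalidParameterError(f"dt {dt}s too coarse for {f} Hz modulation")
    n = int(round(duration / dt))
    t = np.arange(n) * dt

    if profile.paradigm in (Paradigm.POVAR, Paradigm.OVAR):
        from .stimulus import gia_array
        _, gia = gia_array(replace_duration(profile, duration), 1.0 / dt)
        gia = gia[:n]
    else:
        gia = np.tile([0.0, 0.0, profile.gravity], (n, 1))
    omega = _omega_profile(profile, t, tav_stop_time)

    gravity = profile.gravity
    p = (params.canal_time_constant, params.storage_time_constant, params.k_F,
         params.canal_gain_left, params.canal_gain_right, params.otolith_gain,
         params.vor_gain, params.tilt_correction_gain, params.storage_coupling,
         params.otolith_smc_gain)
    k = max(1, int(round(params.quick_phase_duration / dt)))
    u = np.arange(1, k + 1) / k
    profile_disp = 0.5 * (1.0 - np.cos(np.pi * u))
    qp_weights = np.diff(np.concatenate([[0.0], profile_disp]))  # sums to 1
    eye_pos, eye_vel, om_cw, g_est_traj, qp_t_buf, qp_a_buf, n_qp_total, ok = _simulate_core(
        np.ascontiguousarray(omega), np.ascontiguousarray(gia), dt, gravity,
        params.quick_phase_orbital_limit, params.quick_phase_reset_fraction,
        qp_weights, *p)
    if ok != 0:
        raise SimulationUnstableError(
            "integration diverged (non-finite state or gravity-estimate norm "
            "left the [0.4, 1.6] x gravity stability band)")
    qp_times = qp_t_buf[:n_qp_total]
    qp_amps = qp_a_buf[:n_qp_total]

    if steady_window is None:
        steady_window = (duration / 2.0, duration)
    lo, hi = steady_window
    qp_arr = np.asarray(qp_times)
    n_qp = int(np.count_nonzero((qp_arr >= lo) & (qp_arr < hi))) if len(qp_arr) else 0
    win_mask = (t >= lo) & (t < hi)
    bias = float(np.mean(eye_vel[win_mask])) if win_mask.any() else float("nan")
    metrics = NystagmusMetrics(fpn_frequency=n_qp / (hi - lo), n_quick_phases=n_qp,
                               bias_velocity=bias, window_duration=hi - lo)
    return SimulationResult(times=t, eye_position=eye_pos, eye_velocity=eye_vel,
                            omega_est_cw=om_cw, g_est=g_est_traj,
                            quick_phase_times=qp_arr,
                            quick_phase_amplitudes=np.asarray(qp_amps),
                            metrics=metrics, steady_window=(float(lo), float(hi)))


def replace_duration(profile: StimulusProfile, duration: float) -> StimulusProfile:
    from dataclasses import replace as dc_replace
    return dc_replace(profile, duration=duration) if duration != profile.duration else profile


def scenario(name: Scenario | str, base: VSMParams = VSMParams(),
             lesion_gain: float = 0.2, attenuation: float = 0.5) -> VSMParams:
    """Model parameters for a named lesion/treatment scenario."""
    name = Scenario(name)
    if name in (Scenario.CONTROL, Scenario.CUSTOM):
        return base
    if name is Scenario.CANAL_NULL:
        return replace(base, canal_gain_left=0.0, canal_gain_right=0.0)
    if name is Scenario.OTOLITH_NULL:
        return replace(base, otolith_gain=0.0)
    if name is Scenario.UVL_LEFT:
        return replace(base, canal_gain_left=base.canal_gain_left * lesion_gain)
    if name is Scenario.UVL_RIGHT:
        return replace(base, canal_gain_right=base.canal_gain_right * lesion_gain)
    if name is Scenario.STORAGE_ATTENUATED:
        return replace(base, storage_time_constant=base.storage_time_constant * attenuation,
                       k_F=base.k_F * attenuation)
    raise InvalidParameterError(f"unknown scenario {name!r}")
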