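"""Ground-truthed synthetic eye movements and eye-video frames.

The generator emulates the structure of murine eye movements during rotation
tests: a sinusoidal modulation component (SMC) locked to the stimulus
frequency, a constant slow-phase drift (the velocity-storage bias) repeatedly
reset by quick phases ("jerk" nystagmus), and additive measurement noise.
Scenario presets encode the phenotypes the analysis must distinguish:

* ``control`` — full SMC, bias and quick phases.
* ``canal_null`` — semicircular-canal loss: SMC intact, no bias, no quick
  phases during steady state.
* ``otolith_null`` — otolith loss: no SMC and no bias during steady state.
* ``uvl_left`` / ``uvl_right`` — unilateral lesion: quick-phase rate and bias
  attenuated by ``asymmetry_ratio`` when the stimulus beats toward the
  lesioned side (left-UVL suppresses CCW, right-UVL suppresses CW).
* ``storage_attenuated`` — central (velocity-storage) attenuation: bias and
  quick-phase rate reduced, SMC untouched.

Every stochastic element is driven by one integer seed; identical seeds give
bit-identical output.  Ground truth (injected event times and amplitudes,
true bias, SMC amplitude/phase, decay time constant) travels alongside the
trace so detector accuracy is measurable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, InvalidTrajectoryError
from .stimulus import Paradigm, StimulusProfile
from .trace import EyeTrace

DEFAULT_SAMPLING_RATE = 60.0  # Hz; resolves 40 ms quick phases at >2 samples


class Scenario(str, Enum):
    CONTROL = "control"
    CANAL_NULL = "canal_null"
    OTOLITH_NULL = "otolith_null"
    UVL_LEFT = "uvl_left"
    UVL_RIGHT = "uvl_right"
    STORAGE_ATTENUATED = "storage_attenuated"
    CUSTOM = "custom"


@dataclass(frozen=True)
class ScenarioParams:
    """Generator parameters for one lesion/treatment scenario.

    ``bias_velocity`` is specified for CW (positive-direction) stimulation;
    CCW stimulation flips its sign, matching the compensatory slow phase
    always opposing head rotation.  ``asymmetry_ratio`` multiplies both the
    quick-phase rate and the bias magnitude when the stimulus direction is
    the scenario's suppressed one.
    """

    scenario: Scenario = Scenario.CONTROL
    smc_amplitude_v: float = 3.0      # deg, vertical SMC peak amplitude
    smc_amplitude_h: float = 1.0      # deg, horizontal SMC peak amplitude
    bias_velocity: float = -8.0       # deg/s under CW stimulation
    quick_phase_rate: float = 0.8     # Hz, Poisson trigger rate
    asymmetry_ratio: float = 1.0      # rate/bias multiplier, suppressed direction
    noise_sd: float = 0.1             # deg, white position noise
    orbital_limit: float = 15.0       # deg, deterministic reset threshold
    quick_phase_amplitude_mean: float = 10.0  # deg
    quick_phase_amplitude_sd: float = 2.0     # deg
    quick_phase_duration: float = 0.040       # s, half-cosine profile
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.quick_phase_rate < 0:
            raise InvalidParameterError("quick_phase_rate must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.orbital_limit <= 0:
            raise InvalidParameterError("orbital_limit must be > 0")
        if self.asymmetry_ratio <= 0:
            raise InvalidParameterError("asymmetry_ratio must be > 0")
        if self.quick_phase_duration <= 0:
            raise InvalidParameterError("quick_phase_duration must be > 0")

    @property
    def suppressed_direction(self) -> int:
        """Stimulus direction whose quick phases are attenuated (0 = none)."""
        if self.scenario is Scenario.UVL_LEFT:
            return -1  # CCW suppressed in left lesions
        if self.scenario is Scenario.UVL_RIGHT:
            return +1
        return 0


def scenario_params(name: Scenario | str, seed: int = 0, **overrides) -> ScenarioParams:
    """Preset :class:`ScenarioParams` for a named scenario."""
    name = Scenario(name)
    base = ScenarioParams(scenario=name, seed=seed)
    if name is Scenario.CANAL_NULL:
        base = replace(base, bias_velocity=0.0, quick_phase_rate=0.0)
    elif name is Scenario.OTOLITH_NULL:
        base = replace(base, smc_amplitude_v=0.0, smc_amplitude_h=0.0,
                       bias_velocity=0.0, quick_phase_rate=0.0)
    elif name in (Scenario.UVL_LEFT, Scenario.UVL_RIGHT):
        base = replace(base, asymmetry_ratio=0.6,
                       smc_amplitude_v=base.smc_amplitude_v * 0.7,
                       smc_amplitude_h=base.smc_amplitude_h * 0.7)
    elif name is Scenario.STORAGE_ATTENUATED:
        base = replace(base, bias_velocity=base.bias_velocity * 0.5,
                       quick_phase_rate=base.quick_phase_rate * 0.5)
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Injected-event record returned with every synthetic trace."""

    quick_phase_onsets: np.ndarray          # s
    quick_phase_amplitudes: np.ndarray      # deg, signed
    true_bias_velocity: float               # deg/s, effective (direction applied)
    true_smc_amplitude_h: float             # deg
    true_smc_amplitude_v: float             # deg
    true_smc_phase: float                   # deg, at the phase reference
    true_time_constant: Optional[float] = None  # s, TAV only
    quick_phase_duration: float = 0.040

    @property
    def true_smc_amplitude(self) -> float:
        """Vertical SMC amplitude, the paradigm's otolith readout."""
        return self.true_smc_amplitude_v

    @property
    def n_quick_phases(self) -> int:
        return len(self.quick_phase_onsets)


def _half_cosine(t_rel: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Quick-phase displacement profile: 0 -> amplitude over ``duration``."""
    out = np.where(t_rel >= duration, amplitude,
                   0.5 * amplitude * (1.0 - np.cos(np.pi * np.clip(t_rel, 0, duration) / duration)))
    return np.where(t_rel < 0, 0.0, out)


def _inject_quick_phases(t: np.ndarray, slow_position: np.ndarray,
                         scenario: ScenarioParams, rate: float, bias_sign: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, list[float], list[float]]:
    """Superimpose stochastic + orbital-reset quick phases on a slow-phase path.

    ``slow_position`` is the quick-phase-free horizontal position (SMC +
    drift).  Returns the quick-phase displacement series plus event onsets
    and signed amplitudes.  Triggers: a Poisson process at ``rate`` and a
    deterministic reset whenever total position exceeds the orbital limit.
    Quick phases beat opposite to the slow-phase drift (``-bias_sign``);
    orbital resets always re-center.
    """
    n = len(t)
    fs = 1.0 / (t[1] - t[0]) if n > 1 else 1.0
    dur = scenario.quick_phase_duration
    p_trigger = rate / fs
    uniforms = rng.random(n)           # one draw per sample keeps determinism simple
    qp = np.zeros(n)
    onsets: list[float] = []
    amps: list[float] = []
    last_onset = -np.inf
    for i in range(n):
        pos = slow_position[i] + qp[i]
        poisson_hit = uniforms[i] < p_trigger
        orbital_hit = abs(pos) > scenario.orbital_limit
        if not (poisson_hit or orbital_hit):
            continue
        if t[i] - last_onset <= dur + 2.0 / fs:  # refractory: one event at a time
            continue
        magnitude = abs(rng.normal(scenario.quick_phase_amplitude_mean,
                                   scenario.quick_phase_amplitude_sd))
        magnitude = max(magnitude, 1.0)
        if orbital_hit:
            sign = -np.sign(pos)
        elif bias_sign != 0:
            sign = -bias_sign
        else:
            sign = -np.sign(pos) if pos != 0 else rng.choice([-1.0, 1.0])
        amp = sign * magnitude
        qp[i:] += _half_cosine(t[i:] - t[i], amp, dur)
        onsets.append(float(t[i]))
        amps.append(float(amp))
        last_onset = t[i]
    return qp, onsets, amps


def generate_trace(profile: StimulusProfile, scenario: ScenarioParams,
                   sampling_rate: float = DEFAULT_SAMPLING_RATE) -> tuple[EyeTrace, GroundTruth]:
    """Synthesize one rotation-test recording with ground truth.

    Horizontal channel: SMC sinusoid at the stimulus frequency + slow-phase
    drift at the (direction-resolved) bias velocity + resetting quick phases
    + Gaussian noise.  Vertical channel: SMC sinusoid + noise.
    """
    f = profile.modulation_frequency_hz
    if profile.paradigm is Paradigm.POVAR and f > 0 and profile.duration < 10.0 / f:
        raise InsufficientDataError(
            f"duration {profile.duration}s < 10 stimulus cycles ({10.0 / f:.0f}s)")
    rng = np.random.default_rng(scenario.seed)
    n = int(round(profile.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    direction = profile.direction if profile.direction != 0 else 1

    phase = 2.0 * np.pi * f * direction * (t - profile.phase_reference)
    smc_h = scenario.smc_amplitude_h * np.sin(phase)
    smc_v = scenario.smc_amplitude_v * np.sin(phase)

    suppress = scenario.asymmetry_ratio if direction == scenario.suppressed_direction else 1.0
    bias = scenario.bias_velocity * direction * suppress
    rate = scenario.quick_phase_rate * suppress

    slow = smc_h + bias * t
    qp, onsets, amps = _inject_quick_phases(t, slow, scenario, rate, float(np.sign(bias)), rng)

    noise_h = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
    noise_v = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
    trace = EyeTrace(timestamps=t, horizontal=slow + qp + noise_h,
                     vertical=smc_v + noise_v, sampling_rate=sampling_rate)
    truth = GroundTruth(
        quick_phase_onsets=np.asarray(onsets),
        quick_phase_amplitudes=np.asarray(amps),
        true_bias_velocity=float(bias),
        true_smc_amplitude_h=scenario.smc_amplitude_h,
        true_smc_amplitude_v=scenario.smc_amplitude_v,
        true_smc_phase=0.0,
        quick_phase_duration=scenario.quick_phase_duration,
    )
    return trace, truth


def generate_tav_trace(profile: StimulusProfile, tau: float, scenario: ScenarioParams,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE,
                       step_time: float = 5.0, vor_gain: float = 0.8
                       ) -> tuple[EyeTrace, GroundTruth]:
    """Trapezoidal-velocity (TAV) recording: exponential post-step decay.

    Slow-phase velocity is 0 before ``step_time`` and
    ``v0 * exp(-(t - step_time)/tau)`` after it, with
    ``v0 = -sign(plateau) * vor_gain * |plateau|`` (compensatory direction).
    Quick phases are superimposed by orbital-limit resets plus the
    scenario's Poisson rate; ``true_time_constant`` records ``tau``.
    """
    if profile.paradigm is not Paradigm.TAV:
        raise InvalidParameterError("generate_tav_trace requires a TAV profile")
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    rng = np.random.default_rng(scenario.seed)
    n = int(round(profile.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    plateau = profile.tav_plateau_velocity
    v0 = -np.sign(plateau) * vor_gain * abs(plateau)
    vel = np.where(t >= step_time, v0 * np.exp(-(t - step_time) / tau), 0.0)
    slow = np.concatenate([[0.0], np.cumsum(0.5 * (vel[1:] + vel[:-1]) * np.diff(t))])

    qp, onsets, amps = _inject_quick_phases(t, slow, scenario, scenario.quick_phase_rate,
                                            float(np.sign(v0)), rng)
    noise_h = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
    noise_v = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
    trace = EyeTrace(timestamps=t, horizontal=slow + qp + noise_h,
                     vertical=np.zeros(n) + noise_v, sampling_rate=sampling_rate)
    truth = GroundTruth(
        quick_phase_onsets=np.asarray(onsets),
        quick_phase_amplitudes=np.asarray(amps),
        true_bias_velocity=0.0,
        true_smc_amplitude_h=0.0, true_smc_amplitude_v=0.0, true_smc_phase=0.0,
        true_time_constant=float(tau),
        quick_phase_duration=scenario.quick_phase_duration,
    )
    return trace, truth


def generate_frames(pupil_trajectory: Sequence[tuple[float, float]],
                    frame_shape: tuple[int, int] = (160, 240),
                    pupil_axes: tuple[float, float] = (22.0, 18.0),
                    noise_sd: float = 0.0,
                    iris_intensity: float = 0.70,
                    pupil_intensity: float = 0.08,
                    highlight: bool = False,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render a stack of synthetic eye frames with known pupil centers.

    Each frame is a bright iris background with a dark filled ellipse at the
    commanded ``(x, y)`` center (pixel coordinates, x right / y down), an
    optional specular highlight, and Gaussian pixel noise.  Ellipse edges are
    rendered with a one-pixel soft ramp so sub-pixel centers survive
    rasterization.  Returns ``(frames (n, H, W) float32 in [0, 1],
    centers (n, 2))``.
    """
    centers = np.asarray(list(pupil_trajectory), dtype=float).reshape(-1, 2)
    h, w = frame_shape
    a, b = pupil_axes  # semi-axes along x, y
    if len(centers):
        margin = max(a, b)
        if (np.any(centers[:, 0] - margin < 0) or np.any(centers[:, 0] + margin > w - 1)
                or np.any(centers[:, 1] - margin < 0) or np.any(centers[:, 1] + margin > h - 1)):
            raise InvalidTrajectoryError("pupil trajectory too close to the frame edge")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((len(centers), h, w), dtype=np.float32)
    for i, (cx, cy) in enumerate(centers):
        # signed "radius" in ellipse units; soft edge of ~1 px width
        r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
        edge_px = 1.0 / min(a, b)
        inside = np.clip((1.0 - r) / edge_px, -1.0, 1.0) * 0.5 + 0.5
        img = iris_intensity + (pupil_intensity - iris_intensity) * inside
        if highlight:
            hr = np.sqrt((xx - (cx + a * 0.3)) ** 2 + (yy - (cy - b * 0.3)) ** 2)
            img = np.where(hr < 2.5, 0.95, img)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)
    return frames, centers
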