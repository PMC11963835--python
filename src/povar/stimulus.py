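"""Dual-axis rotation kinematics.

A pseudo-OVAR (pOVAR) turntable spins the animal about an Earth-vertical main
axis at an eccentric radius while the animal counter-rotates about its own
(eccentric) axis.  The centrifugal acceleration of the main-axis rotation,
added to gravity, tilts the gravito-inertial acceleration (GIA) away from the
head's dorso-ventral axis by a constant angle

    theta = arctan(omega_M^2 * r / g)

exactly as a conventional OVAR tilt would, while the eccentric-axis velocity
sets the frequency at which the GIA sweeps around the head:

    f = |V_E| / 360  (Hz, one revolution = 360 deg).

Sign convention used throughout the package: clockwise viewed from above is
positive angular velocity.  Head-frame axes are naso-occipital (+nose),
interaural (+left), dorso-ventral (+up).  Angles are degrees at every public
boundary; radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidParameterError, UnsupportedParadigmError

STANDARD_GRAVITY = 9.80665  # m/s^2


class Paradigm(str, Enum):
    POVAR = "pOVAR"
    OVAR = "OVAR"
    AVOR = "aVOR"
    TAV = "TAV"


@dataclass(frozen=True)
class StimulusProfile:
    """Parameters of one rotation test.

    Parameters
    ----------
    paradigm
        One of pOVAR, OVAR, aVOR, TAV.
    main_axis_velocity
        Signed main-axis angular velocity in deg/s (+ = CW from above).
        Determines the simulated tilt angle in pOVAR.
    eccentric_axis_velocity
        Signed eccentric-axis angular velocity in deg/s; its magnitude sets
        the otolith modulation frequency, its sign the stimulus direction.
    radius
        Main-axis rotation radius in metres (head to main axis).
    duration
        Recording duration in seconds.
    gravity
        Local gravity in m/s^2; standard gravity by default.
    phase_reference
        Absolute-phase reference time in seconds (e.g. an LED flash);
        azimuth zero of the GIA sweep is anchored here.
    tav_plateau_velocity, tav_ramp
        Trapezoidal-velocity parameters, used by the TAV paradigm only.
    """

    paradigm: Paradigm
    main_axis_velocity: float = 0.0
    eccentric_axis_velocity: float = 0.0
    radius: float = 0.17
    duration: float = 180.0
    gravity: float = STANDARD_GRAVITY
    phase_reference: float = 0.0
    tav_plateau_velocity: float = 100.0
    tav_ramp: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "paradigm", Paradigm(self.paradigm))
        if self.radius <= 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.gravity <= 0:
            raise InvalidParameterError(f"gravity must be > 0, got {self.gravity}")
        if self.paradigm is Paradigm.POVAR and (
            self.main_axis_velocity == 0 or self.eccentric_axis_velocity == 0
        ):
            raise InvalidParameterError("pOVAR requires nonzero velocities on both axes")

    @property
    def tilt_angle(self) -> float:
        """Equivalent conventional-OVAR tilt angle in degrees."""
        return equivalent_tilt_angle(self.main_axis_velocity, self.radius, self.gravity)

    @property
    def modulation_frequency_hz(self) -> float:
        return modulation_frequency(self.eccentric_axis_velocity)

    @property
    def direction(self) -> int:
        """Stimulus direction: +1 CW, -1 CCW, 0 static (eccentric axis)."""
        return int(np.sign(self.eccentric_axis_velocity))


@dataclass(frozen=True)
class GIASample:
    """Head-frame gravito-inertial acceleration at one instant."""

    time: float
    gia_head_frame: np.ndarray = field(repr=False)  # (naso-occipital, interaural, dorso-ventral), m/s^2
    tilt_angle: float = 0.0


def equivalent_tilt_angle(main_axis_velocity: float, radius: float,
                          gravity: float = STANDARD_GRAVITY) -> float:
    """Tilt angle (deg) of the GIA produced by main-axis rotation.

    ``arctan(omega^2 r / g)`` with omega the main-axis speed in rad/s: the
    direction of the resultant of gravity and the centrifugal acceleration
    relative to Earth-vertical, i.e. the tilt a conventional OVAR test would
    need to produce the same otolith stimulus.
    """
    if radius <= 0:
        raise InvalidParameterError(f"radius must be > 0, got {radius}")
    if gravity <= 0:
        raise InvalidParameterError(f"gravity must be > 0, got {gravity}")
    omega = np.deg2rad(abs(main_axis_velocity))
    return float(np.rad2deg(np.arctan2(omega**2 * radius, gravity)))


def nominal_tilt_angle(main_axis_velocity: float, radius: float,
                       gravity: float = STANDARD_GRAVITY, step: float = 10.0) -> float:
    """Tilt angle rounded to the nearest multiple of ``step`` degrees.

    Turntable protocols label velocity settings with round tilt angles
    (10, 20, 30, 40 deg); the raw arctan values differ by a degree or so.
    """
    return float(step * round(equivalent_tilt_angle(main_axis_velocity, radius, gravity) / step))


def modulation_frequency(eccentric_axis_velocity: float) -> float:
    """Otolith modulation frequency in Hz: |V_E| / 360."""
    return abs(eccentric_axis_velocity) / 360.0


def gia_magnitude(profile: StimulusProfile) -> float:
    """Constant magnitude of the head-frame GIA, m/s^2."""
    omega = np.deg2rad(abs(profile.main_axis_velocity))
    return float(np.hypot(profile.gravity, omega**2 * profile.radius))


def gia_timecourse(profile: StimulusProfile, sampling_rate: float) -> list[GIASample]:
    """Head-frame GIA samples over the whole recording.

    The GIA vector keeps a constant dorso-ventral component equal to gravity
    and a horizontal-plane component ``omega_M^2 r`` that sweeps around the
    head at the modulation frequency, in the direction set by the sign of the
    eccentric-axis velocity.  Azimuth zero (GIA tilted toward the nose) is at
    ``phase_reference``.
    """
    if profile.paradigm not in (Paradigm.POVAR, Paradigm.OVAR):
        raise UnsupportedParadigmError(
            f"gia_timecourse supports pOVAR/OVAR, got {profile.paradigm.value}")
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be > 0")
    n = int(round(profile.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    omega = np.deg2rad(abs(profile.main_axis_velocity))
    a_h = omega**2 * profile.radius  # horizontal (centrifugal) component
    f = profile.modulation_frequency_hz
    direction = profile.direction if profile.direction != 0 else 1
    azimuth = 2.0 * np.pi * f * direction * (t - profile.phase_reference)
    tilt = float(np.rad2deg(np.arctan2(a_h, profile.gravity)))
    naso = a_h * np.cos(azimuth)
    inter = a_h * np.sin(azimuth)
    dorso = np.full(n, profile.gravity)
    return [
        GIASample(time=float(t[i]),
                  gia_head_frame=np.array([naso[i], inter[i], dorso[i]]),
                  tilt_angle=tilt)
        for i in range(n)
    ]


def gia_array(profile: StimulusProfile, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized GIA time course: ``(times (n,), gia (n, 3))`` arrays.

    Same contents as :func:`gia_timecourse`; preferred by the simulator.
    """
    samples = None  # computed inline to avoid building n dataclass objects
    if profile.paradigm not in (Paradigm.POVAR, Paradigm.OVAR):
        raise UnsupportedParadigmError(
            f"gia_array supports pOVAR/OVAR, got {profile.paradigm.value}")
    n = int(round(profile.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    omega = np.deg2rad(abs(profile.main_axis_velocity))
    a_h = omega**2 * profile.radius
    f = profile.modulation_frequency_hz
    direction = profile.direction if profile.direction != 0 else 1
    azimuth = 2.0 * np.pi * f * direction * (t - profile.phase_reference)
    gia = np.column_stack([a_h * np.cos(azimuth),
                           a_h * np.sin(azimuth),
                           np.full(n, profile.gravity)])
    return t, gia
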