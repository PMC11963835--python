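"""Sinusoidal modulation component (SMC) fitting and direction asymmetry.

During OVAR the otoliths are swept by a rotating gravito-inertial vector,
imprinting a sinusoid at the stimulus frequency on the eye-position trace
(vertical SMC tracks tilt, horizontal SMC translation).  The fit is linear
because the frequency is set by the apparatus: on slow-labelled samples we
solve ``y = dc + drift*t + A sin(2 pi f t) + B cos(2 pi f t)`` and report
amplitude ``hypot(A, B)``, with the drift column absorbing residual bias
velocity so it cannot inflate the amplitude.

The CW/CCW asymmetry statistic normalizes fast-phase frequency between
rotation directions; a unilateral lesion suppresses the quick phases of one
direction, pushing the lesion-oriented ratio below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (InsufficientDataError, UndefinedGainError,
                     UndefinedRatioError)
from .segmentation import NystagmusMetrics, PhaseLabel, PhaseSegmentation
from .stimulus import Paradigm, StimulusProfile
from .trace import EyeTrace


@dataclass(frozen=True)
class SMCFit:
    frequency: float        # Hz, fixed to the stimulus
    amplitude: float        # deg, fitted peak amplitude (>= 0)
    phase: float            # deg in (-180, 180], relative to the phase reference
    dc_offset: float        # deg
    drift: float            # deg/s
    r_squared: float        # NaN when the trace has no variance


@dataclass(frozen=True)
class AsymmetryResult:
    fpn_cw: float           # Hz
    fpn_ccw: float          # Hz
    ratio: float
    orientation: str        # e.g. "CW/CCW": numerator/denominator


def _wrap_phase(phase_deg: float) -> float:
    phase = (phase_deg + 180.0) % 360.0 - 180.0
    return 180.0 if phase == -180.0 else phase


def fit_smc(trace: EyeTrace, seg: Optional[PhaseSegmentation],
            stimulus_frequency: float, phase_reference: float = 0.0,
            channel: str = "horizontal", trim: float = 2.5) -> SMCFit:
    """Fit the stimulus-frequency sinusoid ``A sin(2 pi f (t - t0) + phi)``.

    ``seg=None`` fits position directly over all samples (appropriate for
    the vertical channel, which carries no quick phases):
    ``dc + drift*t + A sin + B cos`` by least squares.

    With a segmentation the horizontal channel is a sawtooth — slow-phase
    drift repeatedly reset by quick phases — whose broadband structure leaks
    into a position-domain sinusoid fit.  The fit therefore moves to the
    velocity domain on slow-labelled samples, where quick phases are excised
    rather than stitched: ``velocity = bias + A w cos(w t + phi)`` is linear
    in the same unknowns, and a trimmed second pass (as in bias estimation)
    rejects filter-ringing residue.  Requires >= 3 stimulus cycles.
    """
    if stimulus_frequency <= 0:
        raise InsufficientDataError("stimulus frequency must be positive for an SMC fit")
    y_full = getattr(trace, channel)
    t = trace.timestamps
    w = 2.0 * np.pi * stimulus_frequency

    if seg is None:
        ts, y = t, y_full
        if len(ts) < 4 or (ts[-1] - ts[0]) < 3.0 / stimulus_frequency:
            raise InsufficientDataError(
                f"need >= 3 stimulus cycles of data at {stimulus_frequency} Hz")
        tr = ts - phase_reference
        design = np.column_stack([np.ones_like(tr), tr, np.sin(w * tr), np.cos(w * tr)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        dc, drift, a_sin, a_cos = coef
        amplitude = float(np.hypot(a_sin, a_cos))
        phase = _wrap_phase(float(np.rad2deg(np.arctan2(a_cos, a_sin))))
        resid = y - design @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        return SMCFit(frequency=stimulus_frequency, amplitude=amplitude, phase=phase,
                      dc_offset=float(dc), drift=float(drift), r_squared=r2)

    lo, hi = seg.analysis_window
    mask = (t >= lo) & (t < hi) & (seg.labels == PhaseLabel.SLOW)
    ts, v = t[mask], seg.velocity[mask]
    if len(ts) < 4 or (ts[-1] - ts[0]) < 3.0 / stimulus_frequency:
        raise InsufficientDataError(
            f"need >= 3 stimulus cycles of slow-phase data at {stimulus_frequency} Hz")
    tr = ts - phase_reference
    design = np.column_stack([np.ones_like(tr), np.sin(w * tr), np.cos(w * tr)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    if trim > 0:
        resid = v - design @ coef
        center = np.median(resid)
        mad = np.median(np.abs(resid - center))
        if mad > 0:
            keepers = np.abs(resid - center) <= trim * 1.4826 * mad
            if keepers.sum() >= max(4, int(0.5 * len(v))):
                design, v = design[keepers], v[keepers]
                coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    bias, c_sin, c_cos = coef
    # velocity of A sin(w t + phi) is A w cos(w t + phi) = -A w sin(phi) sin + A w cos(phi) cos
    amplitude = float(np.hypot(c_sin, c_cos) / w)
    phase = _wrap_phase(float(np.rad2deg(np.arctan2(-c_sin, c_cos))))
    resid = v - design @ coef
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    dc_offset = float(np.mean(y_full[mask]))
    return SMCFit(frequency=stimulus_frequency, amplitude=amplitude, phase=phase,
                  dc_offset=dc_offset, drift=float(bias), r_squared=r2)


def smc_gain(fit: SMCFit, profile: StimulusProfile) -> float:
    """SMC amplitude normalized by stimulus magnitude.

    For pOVAR/OVAR the denominator is the equivalent tilt angle (deg); for
    aVOR it is the oscillation amplitude implied by the eccentric-axis
    velocity at the stimulus frequency.  Dimensionless (deg/deg).
    """
    if profile.paradigm in (Paradigm.POVAR, Paradigm.OVAR):
        denom = profile.tilt_angle
    else:
        f = profile.modulation_frequency_hz
        denom = (abs(profile.eccentric_axis_velocity) / (2.0 * np.pi * f)) if f > 0 else 0.0
    if denom == 0:
        raise UndefinedGainError("stimulus amplitude is zero; gain undefined")
    return fit.amplitude / denom


def asymmetry_ratio(metrics_cw: NystagmusMetrics, metrics_ccw: NystagmusMetrics,
                    orientation: str = "CW/CCW") -> AsymmetryResult:
    """Normalized fast-phase-frequency ratio between rotation directions.

    ``orientation`` names numerator/denominator ("CW/CCW" or "CCW/CW"); the
    lesion-consistent choice (left lesion: CCW/CW, right lesion: CW/CCW)
    puts the suppressed direction on top, so lesions give ratios < 1.
    """
    if orientation not in ("CW/CCW", "CCW/CW"):
        raise ValueError(f"orientation must be 'CW/CCW' or 'CCW/CW', got {orientation!r}")
    num, den = ((metrics_cw.fpn_frequency, metrics_ccw.fpn_frequency)
                if orientation == "CW/CCW"
                else (metrics_ccw.fpn_frequency, metrics_cw.fpn_frequency))
    if den == 0:
        raise UndefinedRatioError(f"denominator of {orientation} is zero")
    return AsymmetryResult(fpn_cw=metrics_cw.fpn_frequency,
                           fpn_ccw=metrics_ccw.fpn_frequency,
                           ratio=num / den, orientation=orientation)
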