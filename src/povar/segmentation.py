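"""Fast-/slow-phase separation by filtered differentiation and thresholding.

Position traces are zero-phase low-pass filtered, differentiated twice, and
quick phases are seeded where |acceleration| exceeds a threshold, then grown
over the contiguous samples where |velocity| stays above a velocity
threshold.  Events shorter than a minimum duration are discarded and events
closer than a refractory gap are merged.  From the labelling follow the two
scalar readouts of rotational nystagmus: the fast-phase frequency (events
per second in the analysis window) and the bias (mean slow-phase) velocity
after removing the stimulus-frequency modulation.

Default thresholds suit murine quick phases (tens of ms, hundreds of deg/s)
riding on 0.1-0.4 Hz slow modulation; all are exposed on
:class:`SegmentationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import (InvalidParameterError, InvalidWindowError,
                     UnreliableEstimateError)
from .trace import QUALITY_ARTIFACT, EyeTrace


class PhaseLabel(IntEnum):
    SLOW = 0
    FAST = 1
    ARTIFACT = 2


@dataclass(frozen=True)
class SegmentationConfig:
    filter_cutoff: float = 10.0           # Hz, zero-phase Butterworth low-pass
    filter_order: int = 4
    velocity_threshold: float = 30.0      # deg/s, event growth
    acceleration_threshold: float = 1000.0  # deg/s^2, event seeding
    min_duration: float = 0.015           # s, shortest retained event
    refractory: float = 0.050             # s, events closer than this merge
    pad: float = 0.035                    # s, label margin around each event
    baseline_window: float = 0.6          # s, running-median slow-velocity baseline
    analysis_start: float = 60.0          # s, discard the spin-up transient
    analysis_end: Optional[float] = None  # s, None = end of trace


@dataclass(frozen=True)
class QuickPhaseEvent:
    onset: float          # s
    offset: float         # s
    amplitude: float      # deg, signed displacement over the event
    peak_velocity: float  # deg/s, signed extremum

    @property
    def direction(self) -> str:
        return "positive" if self.amplitude >= 0 else "negative"


@dataclass
class PhaseSegmentation:
    labels: np.ndarray                 # per-sample PhaseLabel codes
    events: list[QuickPhaseEvent]
    velocity: np.ndarray               # deg/s, filtered derivative
    acceleration: np.ndarray           # deg/s^2
    config: SegmentationConfig
    analysis_window: tuple[float, float]

    def events_in_window(self) -> list[QuickPhaseEvent]:
        lo, hi = self.analysis_window
        return [e for e in self.events if lo <= e.onset < hi]


@dataclass(frozen=True)
class NystagmusMetrics:
    fpn_frequency: float   # Hz
    n_quick_phases: int
    bias_velocity: float   # deg/s, signed; NaN when not computed
    window_duration: float # s


def smooth_and_differentiate(trace: EyeTrace, cutoff: float = 10.0,
                             order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase low-pass the horizontal channel, return (velocity, acceleration).

    Forward-backward Butterworth filtering keeps event onsets unlagged;
    derivatives are central differences aligned to the input timestamps.
    """
    nyquist = trace.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, trace.horizontal)
    dt = 1.0 / trace.sampling_rate
    velocity = np.gradient(smoothed, dt)
    acceleration = np.gradient(velocity, dt)
    return velocity, acceleration


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (inclusive) index pairs of True runs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    stops = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def segment_phases(trace: EyeTrace, config: SegmentationConfig = SegmentationConfig(),
                   analysis_window: Optional[tuple[float, float]] = None) -> PhaseSegmentation:
    """Label every sample slow/fast/artifact and list quick-phase events."""
    t = trace.timestamps
    if analysis_window is None:
        start = min(config.analysis_start, max(t[-1] - 1.0, t[0]))
        analysis_window = (start, config.analysis_end if config.analysis_end is not None
                           else float(t[-1]) + 0.5 / trace.sampling_rate)
    lo, hi = analysis_window
    if hi <= lo or hi <= t[0] or lo > t[-1]:
        raise InvalidWindowError(f"empty analysis window ({lo}, {hi})")

    velocity, acceleration = smooth_and_differentiate(
        trace, config.filter_cutoff, config.filter_order)
    fs = trace.sampling_rate
    # quick phases are excursions from the local slow-phase velocity, not from
    # zero: a running median tracks the slow-phase baseline (SMC, post-step
    # decay) so large compensatory velocities are not mislabelled fast
    base_n = max(3, int(round(config.baseline_window * fs)) | 1)
    baseline = ndimage.median_filter(velocity, size=base_n, mode="nearest")
    deviation = velocity - baseline
    seeds = np.abs(acceleration) > config.acceleration_threshold
    grow = np.abs(deviation) > config.velocity_threshold

    # each velocity run containing at least one acceleration seed is a candidate
    candidates = [(a, b) for a, b in _runs(grow) if seeds[a:b + 1].any()]

    # merge candidates separated by less than the refractory gap (fragments of
    # one event whose velocity briefly dipped under the threshold)
    joined: list[list[int]] = []
    for a, b in candidates:
        if joined and (a - joined[-1][1]) / fs < config.refractory:
            joined[-1][1] = b
        else:
            joined.append([a, b])

    # a merged run holding several distinct |velocity| peaks is a cluster of
    # quick phases too close for the filter to separate: split at the
    # inter-peak velocity minima
    merged: list[tuple[int, int]] = []
    peak_distance = max(1, int(round(config.refractory * fs)))
    for a, b in joined:
        speed = np.abs(deviation[a:b + 1])
        peaks, _ = signal.find_peaks(speed, height=config.velocity_threshold,
                                     distance=peak_distance)
        if len(peaks) <= 1:
            merged.append((a, b))
            continue
        bounds = [a]
        for p, q in zip(peaks[:-1], peaks[1:]):
            bounds.append(a + p + int(np.argmin(speed[p:q + 1])))
        bounds.append(b)
        for lo_i, hi_i in zip(bounds[:-1], bounds[1:]):
            merged.append((lo_i, hi_i))

    min_samples = max(1, int(round(config.min_duration * fs)))
    events: list[QuickPhaseEvent] = []
    labels = np.full(len(t), PhaseLabel.SLOW, dtype=int)
    pad_samples = int(round(config.pad * fs))
    for a, b in merged:
        if b - a + 1 < min_samples:
            continue
        seg_vel = velocity[a:b + 1]
        peak = float(seg_vel[np.argmax(np.abs(seg_vel))])
        amplitude = float(trace.horizontal[min(b + 1, len(t) - 1)] - trace.horizontal[max(a - 1, 0)])
        if amplitude == 0.0:
            amplitude = float(np.sign(peak)) * 1e-9
        events.append(QuickPhaseEvent(onset=float(t[a]), offset=float(t[b]),
                                      amplitude=amplitude, peak_velocity=peak))
        labels[max(a - pad_samples, 0):min(b + pad_samples, len(t) - 1) + 1] = PhaseLabel.FAST

    if trace.quality is not None:
        labels[trace.quality == QUALITY_ARTIFACT] = PhaseLabel.ARTIFACT

    return PhaseSegmentation(labels=labels, events=events, velocity=velocity,
                             acceleration=acceleration, config=config,
                             analysis_window=(float(lo), float(hi)))


def fpn_frequency(seg: PhaseSegmentation,
                  trace: Optional[EyeTrace] = None) -> NystagmusMetrics:
    """Fast-phase nystagmus frequency: events per second of analysis window."""
    lo, hi = seg.analysis_window
    window = hi - lo
    if window <= 0:
        raise InvalidWindowError("analysis window has non-positive duration")
    n = len(seg.events_in_window())
    return NystagmusMetrics(fpn_frequency=n / window, n_quick_phases=n,
                            bias_velocity=float("nan"), window_duration=window)


def bias_velocity(trace: EyeTrace, seg: PhaseSegmentation,
                  stimulus_frequency: float, trim: float = 2.5) -> float:
    """Mean slow-phase velocity after removing the stimulus-frequency component.

    Least-squares fit of ``dc + A sin + B cos`` (at the stimulus frequency)
    to the velocity series over slow-labelled samples inside the analysis
    window; the dc term is the bias.  The fit is run twice: residuals beyond
    ``trim`` robust standard deviations (MAD-scaled) of the first pass are
    dropped before refitting, which removes the zero-phase filter's ringing
    lobes flanking each quick phase.  With a zero stimulus frequency the fit
    degenerates to a (trimmed) slow-sample mean.
    """
    lo, hi = seg.analysis_window
    t = trace.timestamps
    in_window = (t >= lo) & (t < hi)
    slow = in_window & (seg.labels == PhaseLabel.SLOW)
    if slow.sum() < 0.5 * in_window.sum():
        raise UnreliableEstimateError(
            f"only {slow.sum()}/{in_window.sum()} window samples are slow-labelled")
    v = seg.velocity[slow]
    ts = t[slow]
    if stimulus_frequency > 0:
        w = 2.0 * np.pi * stimulus_frequency
        design = np.column_stack([np.ones_like(ts), np.sin(w * ts), np.cos(w * ts)])
    else:
        design = np.ones((len(ts), 1))
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    if trim > 0:
        resid = v - design @ coef
        center = np.median(resid)
        mad = np.median(np.abs(resid - center))
        if mad > 0:
            keep = np.abs(resid - center) <= trim * 1.4826 * mad
            if keep.sum() >= max(len(design[0]) + 1, int(0.5 * len(v))):
                coef, *_ = np.linalg.lstsq(design[keep], v[keep], rcond=None)
    return float(coef[0])
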