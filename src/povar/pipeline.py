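"""End-to-end recording analysis and paired-direction comparison.

``analyze_recording`` composes the pipeline — (optional) pupil tracking,
phase segmentation, fast-phase frequency, bias velocity, SMC fits, and for
TAV recordings the time-constant fit — into one :class:`NystagmusReport`.
The effective configuration is hashed into the report so any number in it
is traceable to the exact thresholds that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import IncompatibleRecordingsError
from .modulation import AsymmetryResult, SMCFit, asymmetry_ratio, fit_smc, smc_gain
from .pupil import CalibrationModel, ThresholdSpec, track_video
from .segmentation import (NystagmusMetrics, SegmentationConfig, bias_velocity,
                           fpn_frequency, segment_phases)
from .stimulus import Paradigm, StimulusProfile
from .timeconstant import TimeConstantFit, fit_time_constant, slow_phase_envelope
from .trace import EyeTrace


@dataclass(frozen=True)
class AnalysisConfig:
    """Single source of every threshold used by one analysis run."""

    segmentation: SegmentationConfig = SegmentationConfig()
    calibration: CalibrationModel = CalibrationModel()
    threshold_spec: ThresholdSpec = "otsu"
    max_gap: int = 3
    tav_step_time: float = 5.0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(
            {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
             for k, v in dataclasses.asdict(self).items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class NystagmusReport:
    recording_id: str
    profile: StimulusProfile
    metrics: NystagmusMetrics
    smc_horizontal: Optional[SMCFit] = None
    smc_vertical: Optional[SMCFit] = None
    smc_gain_vertical: Optional[float] = None
    time_constant: Optional[TimeConstantFit] = None
    asymmetry: Optional[AsymmetryResult] = None
    config_hash: str = ""
    seed: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, Paradigm):
                return obj.value
            return obj
        return clean(dataclasses.asdict(self))

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def analyze_recording(recording: Union[EyeTrace, np.ndarray],
                      profile: StimulusProfile,
                      config: AnalysisConfig = AnalysisConfig(),
                      recording_id: str = "recording") -> NystagmusReport:
    """Analyze one recording (trace, or frame stack to be tracked first).

    pOVAR/OVAR/aVOR recordings get fast-phase frequency, bias velocity and
    SMC fits on both channels; TAV recordings get the post-step
    time-constant fit.  Deterministic given inputs and config.
    """
    warnings: list[str] = []
    if isinstance(recording, EyeTrace):
        trace = recording
    else:
        trace, detections = track_video(recording, config.threshold_spec,
                                        config.calibration,
                                        sampling_rate=60.0, max_gap=config.max_gap)
        n_failed = sum(not d.ok for d in detections)
        if n_failed:
            warnings.append(f"pupil tracking failed on {n_failed} frames")

    f = profile.modulation_frequency_hz
    if profile.paradigm is Paradigm.TAV:
        seg = segment_phases(trace, config.segmentation,
                             analysis_window=(float(trace.timestamps[0]),
                                              float(trace.timestamps[-1]) + 0.5 / trace.sampling_rate))
        metrics = fpn_frequency(seg)
        tc_fit = None
        try:
            env = slow_phase_envelope(trace, seg, step_time=config.tav_step_time)
            tc_fit = fit_time_constant(env)
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            warnings.append(f"time-constant fit failed: {exc}")
        return NystagmusReport(recording_id=recording_id, profile=profile,
                               metrics=metrics, time_constant=tc_fit,
                               config_hash=config.hash(), seed=config.seed,
                               warnings=warnings)

    seg = segment_phases(trace, config.segmentation)
    metrics = fpn_frequency(seg)
    bias = float("nan")
    try:
        bias = bias_velocity(trace, seg, f)
    except Exception as exc:  # noqa: BLE001
        warnings.append(f"bias estimate unreliable: {exc}")
    metrics = NystagmusMetrics(fpn_frequency=metrics.fpn_frequency,
                               n_quick_phases=metrics.n_quick_phases,
                               bias_velocity=bias,
                               window_duration=metrics.window_duration)
    smc_h = smc_v = gain_v = None
    if f > 0:
        try:
            smc_h = fit_smc(trace, seg, f, profile.phase_reference, channel="horizontal")
            smc_v = fit_smc(trace, None, f, profile.phase_reference, channel="vertical")
            gain_v = smc_gain(smc_v, profile)
        except Exception as exc:  # noqa: BLE001
            warnings.append(f"SMC fit failed: {exc}")
    return NystagmusReport(recording_id=recording_id, profile=profile,
                           metrics=metrics, smc_horizontal=smc_h,
                           smc_vertical=smc_v, smc_gain_vertical=gain_v,
                           config_hash=config.hash(), seed=config.seed,
                           warnings=warnings)


#: Fast-phase ratio orientation per lesion side: the suppressed direction on top.
LESION_ORIENTATION = {"control": "CW/CCW", "left": "CCW/CW", "right": "CW/CCW"}


def paired_direction_analysis(report_cw: NystagmusReport,
                              report_ccw: NystagmusReport,
                              lesion_orientation: str = "control") -> AsymmetryResult:
    """CW-vs-CCW fast-phase asymmetry from a pair of recordings.

    ``lesion_orientation`` is ``control``, ``left`` or ``right``; it selects
    the ratio convention (suppressed direction in the numerator, so lesions
    give ratios below 1).
    """
    p_cw, p_ccw = report_cw.profile, report_ccw.profile
    if (p_cw.paradigm != p_ccw.paradigm
            or abs(p_cw.main_axis_velocity) != abs(p_ccw.main_axis_velocity)
            or abs(p_cw.eccentric_axis_velocity) != abs(p_ccw.eccentric_axis_velocity)):
        raise IncompatibleRecordingsError(
            "paired recordings must share paradigm and axis speeds")
    if p_cw.direction <= 0 or p_ccw.direction >= 0:
        raise IncompatibleRecordingsError(
            "expected a CW recording first and a CCW recording second")
    if lesion_orientation not in LESION_ORIENTATION:
        raise ValueError(f"lesion_orientation must be one of {sorted(LESION_ORIENTATION)}")
    return asymmetry_ratio(report_cw.metrics, report_ccw.metrics,
                           LESION_ORIENTATION[lesion_orientation])
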