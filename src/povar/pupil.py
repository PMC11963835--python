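"""Pupil-center detection by threshold segmentation and ellipse fitting.

The mouse pupil is the darkest large structure in an eye image.  Each frame
is binarized (fixed or Otsu threshold), the largest dark connected component
is kept, and an ellipse is fitted to the sub-pixel iso-intensity contour at
the threshold level; its center is the pupil position.  Failures (no dark
region, component too small, several similar-sized dark components, ellipse
fit failure) are encoded in the result — a center is never fabricated.

Pixel coordinates have the origin at the top-left, x right, y down.
Calibration to degrees is a user-supplied linear scale with the vertical
axis flipped so that up is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InvalidParameterError, TrackingFailedError
from .trace import (QUALITY_ARTIFACT, QUALITY_GOOD, QUALITY_INTERPOLATED,
                    EyeTrace)

ThresholdSpec = Union[float, str]  # numeric level or "otsu"


@dataclass(frozen=True)
class PupilDetection:
    frame_index: int
    center: Optional[tuple[float, float]]     # (x, y) px
    semi_axes: Optional[tuple[float, float]]  # (a, b) px, a >= b
    orientation: Optional[float]              # deg, major-axis angle
    ok: bool
    failure_reason: str = "none"  # none|no_dark_region|too_small|multiple_ambiguous|fit_failed


@dataclass(frozen=True)
class CalibrationModel:
    scale: float = 0.2              # deg/px
    origin: tuple[float, float] = (0.0, 0.0)  # px, primary gaze position

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("calibration scale must be > 0")

    def to_degrees(self, center: tuple[float, float]) -> tuple[float, float]:
        """(x, y) px -> (horizontal, vertical) deg; up is positive."""
        h = (center[0] - self.origin[0]) * self.scale
        v = -(center[1] - self.origin[1]) * self.scale
        return h, v


def _resolve_threshold(frame: np.ndarray, threshold_spec: ThresholdSpec) -> float:
    if isinstance(threshold_spec, str):
        if threshold_spec.lower() != "otsu":
            raise InvalidParameterError(f"unknown threshold spec {threshold_spec!r}")
        return float(threshold_otsu(frame))
    return float(threshold_spec)


def detect_pupil(frame: np.ndarray, threshold_spec: ThresholdSpec = "otsu",
                 min_area_fraction: float = 0.001, ambiguity_ratio: float = 0.8,
                 frame_index: int = 0) -> PupilDetection:
    """Locate the pupil in a single-channel intensity image.

    The largest dark connected component above ``min_area_fraction`` of the
    frame is accepted unless a second dark component reaches
    ``ambiguity_ratio`` of its area, in which case the detection fails as
    ambiguous rather than guessing.  The returned center comes from a
    least-squares ellipse fit to the threshold-level iso-contour, which
    preserves sub-pixel position; the component centroid is the fallback
    when the contour fit is degenerate.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidParameterError("detect_pupil expects a single-channel image")

    def fail(reason: str) -> PupilDetection:
        return PupilDetection(frame_index=frame_index, center=None, semi_axes=None,
                              orientation=None, ok=False, failure_reason=reason)

    if frame.max() == frame.min():
        return fail("no_dark_region")
    thr = _resolve_threshold(frame, threshold_spec)
    mask = frame < thr
    if not mask.any():
        return fail("no_dark_region")
    labels = measure.label(mask)
    props = sorted(measure.regionprops(labels), key=lambda p: p.area, reverse=True)
    min_area = min_area_fraction * frame.size
    props = [p for p in props if p.area >= min_area]
    if not props:
        return fail("too_small")
    if len(props) > 1 and props[1].area >= ambiguity_ratio * props[0].area:
        return fail("multiple_ambiguous")
    region = props[0]

    # sub-pixel contour at the threshold level, restricted to this component
    contours = measure.find_contours(frame, thr)
    cy, cx = region.centroid
    best = None
    for contour in contours:
        rows = np.clip(np.round(contour[:, 0]).astype(int), 0, labels.shape[0] - 1)
        cols = np.clip(np.round(contour[:, 1]).astype(int), 0, labels.shape[1] - 1)
        votes = np.count_nonzero(labels[rows, cols] == region.label)
        if votes > len(contour) * 0.25 and (best is None or len(contour) > len(best)):
            best = contour
    center = axes = orientation = None
    if best is not None and len(best) >= 5:
        model = measure.EllipseModel.from_estimate(best[:, ::-1])  # (row, col) -> (x, y)
        if model:
            (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
            if a > 0 and b > 0:
                if b > a:
                    a, b = b, a
                    theta += np.pi / 2.0
                center = (float(xc), float(yc))
                axes = (float(a), float(b))
                orientation = float(np.rad2deg(theta) % 180.0)
    if center is None:
        # moments-based fallback: centroid + equivalent ellipse of the region
        a = region.major_axis_length / 2.0
        b = region.minor_axis_length / 2.0
        if a <= 0 or b <= 0:
            return fail("fit_failed")
        center = (float(cx), float(cy))
        axes = (float(a), float(b))
        orientation = float(np.rad2deg(-region.orientation) % 180.0)
    h, w = frame.shape
    if not (0 <= center[0] < w and 0 <= center[1] < h):
        return fail("fit_failed")
    return PupilDetection(frame_index=frame_index, center=center, semi_axes=axes,
                          orientation=orientation, ok=True)


def track_video(frames: Union[np.ndarray, Sequence[np.ndarray]],
                threshold_spec: ThresholdSpec = "otsu",
                calibration: CalibrationModel = CalibrationModel(),
                sampling_rate: float = 60.0,
                max_gap: int = 3) -> tuple[EyeTrace, list[PupilDetection]]:
    """Run pupil detection on every frame and assemble a calibrated trace.

    Failed frames are linearly interpolated when the gap is at most
    ``max_gap`` samples (flagged interpolated) and flagged artifact
    otherwise; the trace always has one sample per frame.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise InvalidParameterError("track_video needs at least 2 frames")
    detections = [detect_pupil(f, threshold_spec, frame_index=i)
                  for i, f in enumerate(frames)]
    n = len(detections)
    h = np.full(n, np.nan)
    v = np.full(n, np.nan)
    for i, det in enumerate(detections):
        if det.ok:
            h[i], v[i] = calibration.to_degrees(det.center)
    good = ~np.isnan(h)
    if not good.any():
        raise TrackingFailedError("pupil detection failed on every frame")
    idx = np.arange(n)
    h = np.interp(idx, idx[good], h[good])
    v = np.interp(idx, idx[good], v[good])
    quality = np.full(n, QUALITY_GOOD, dtype=int)
    bad = np.flatnonzero(~good)
    if len(bad):
        splits = np.flatnonzero(np.diff(bad) > 1)
        starts = np.concatenate([[0], splits + 1])
        stops = np.concatenate([splits, [len(bad) - 1]])
        for a, b in zip(starts, stops):
            gap = bad[a:b + 1]
            quality[gap] = QUALITY_INTERPOLATED if len(gap) <= max_gap else QUALITY_ARTIFACT
    t = idx / sampling_rate
    return EyeTrace(timestamps=t, horizontal=h, vertical=v,
                    sampling_rate=sampling_rate, quality=quality), detections
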