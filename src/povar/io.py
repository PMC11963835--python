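"""Readers/writers for stimulus descriptors, events and frame stacks.

Stimulus profiles round-trip through YAML or JSON with the
:class:`~povar.stimulus.StimulusProfile` field names; quick-phase events go
to CSV; synthetic frames to PNG stacks readable by the tracker.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .segmentation import PhaseSegmentation, QuickPhaseEvent
from .stimulus import StimulusProfile

PathLike = Union[str, Path]


def profile_to_yaml(profile: StimulusProfile, path: PathLike) -> None:
    data = {
        "paradigm": profile.paradigm.value,
        "main_axis_velocity": profile.main_axis_velocity,
        "eccentric_axis_velocity": profile.eccentric_axis_velocity,
        "radius": profile.radius,
        "duration": profile.duration,
        "gravity": profile.gravity,
        "phase_reference": profile.phase_reference,
        "tav_plateau_velocity": profile.tav_plateau_velocity,
        "tav_ramp": profile.tav_ramp,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def profile_from_file(path: PathLike) -> StimulusProfile:
    """Load a stimulus descriptor from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return StimulusProfile(**data)


def events_to_csv(events: list[QuickPhaseEvent], path: PathLike) -> None:
    pd.DataFrame([{
        "onset_s": e.onset,
        "offset_s": e.offset,
        "amplitude_deg": e.amplitude,
        "peak_velocity_dps": e.peak_velocity,
        "direction": e.direction,
    } for e in events]).to_csv(path, index=False)


def events_from_csv(path: PathLike) -> list[QuickPhaseEvent]:
    df = pd.read_csv(path)
    return [QuickPhaseEvent(onset=row.onset_s, offset=row.offset_s,
                            amplitude=row.amplitude_deg,
                            peak_velocity=row.peak_velocity_dps)
            for row in df.itertuples()]


def frames_to_png_stack(frames: np.ndarray, directory: PathLike,
                        prefix: str = "frame") -> list[Path]:
    """Write float [0, 1] frames as 8-bit grayscale PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def frames_from_path(path: PathLike) -> np.ndarray:
    """Load a PNG-stack directory or a video file into float [0, 1] frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = iio.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:  # RGB(A) -> grayscale
        frames = frames[..., :3].mean(axis=-1)
    if frames.max() > 1.0:
        frames = frames / 255.0
    return frames
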