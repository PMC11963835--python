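"""Eye-position trace container and CSV IO.

An :class:`EyeTrace` holds uniformly sampled horizontal/vertical eye position
in degrees.  Gaps never appear as missing rows: failed frames are
interpolated or flagged in ``quality`` (0 = good, 1 = interpolated,
2 = artifact) so downstream labelling can exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

QUALITY_GOOD = 0
QUALITY_INTERPOLATED = 1
QUALITY_ARTIFACT = 2


@dataclass
class EyeTrace:
    timestamps: np.ndarray  # s, uniform
    horizontal: np.ndarray  # deg
    vertical: np.ndarray    # deg
    sampling_rate: float    # Hz
    quality: Optional[np.ndarray] = None  # per-sample quality codes

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        n = len(self.timestamps)
        if len(self.horizontal) != n or len(self.vertical) != n:
            raise InvalidParameterError("trace channels must share one length")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if n >= 2:
            steps = np.diff(self.timestamps)
            if np.any(steps <= 0) or not np.allclose(
                    steps, 1.0 / self.sampling_rate, rtol=0, atol=1e-6 / self.sampling_rate):
                raise InvalidParameterError(
                    "timestamps must increase with constant step 1/sampling_rate")
        if self.quality is None:
            self.quality = np.zeros(n, dtype=int)
        else:
            self.quality = np.asarray(self.quality, dtype=int)
            if len(self.quality) != n:
                raise InvalidParameterError("quality must match trace length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.timestamps,
            "h_deg": self.horizontal,
            "v_deg": self.vertical,
            "quality": self.quality,
        })

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "EyeTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise InvalidParameterError("trace CSV needs at least 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        quality = df["quality"].to_numpy(dtype=int) if "quality" in df else None
        return cls(timestamps=t,
                   horizontal=df["h_deg"].to_numpy(dtype=float),
                   vertical=df["v_deg"].to_numpy(dtype=float),
                   sampling_rate=fs, quality=quality)
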