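"""Shared containers and primitives for tremor kinematics analysis.

The two raw-data containers (:class:`PenTrace`, :class:`AccelStream`) mirror
what the acquisition hardware produces: timestamped stylus samples from a
digitizing tablet, and a tri-axial wrist accelerometer stream at a nominal
128 Hz.  Both round-trip losslessly through the plain-CSV dialects defined in
:mod:`tremorkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Nominal tablet sampling rate (median inter-sample frequency), Hz.
TABLET_FS = 142.0
#: Accelerometer sampling rate, Hz.
ACCEL_FS = 128.0

CONDITIONS = ("none", "low", "high")
TASKS = ("rectangle", "spiral", "star", "elelelel", "handwriting")


@dataclass
class PenTrace:
    """Ordered stylus samples for one task repetition.

    ``pen`` is 1 while the stylus touches the tablet; maximal pen-down runs
    define strokes.  Coordinates are in pixels, time in seconds.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pen: np.ndarray
    participant_id: str = ""
    task_id: str = ""
    condition: str = ""
    repetition: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pen = np.asarray(self.pen, dtype=int)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.pen) == n):
            raise ValueError("PenTrace columns must have equal length")
        if n and np.any(np.diff(self.t) <= 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValueError(f"PenTrace timestamps must be strictly increasing (sample {bad})")
        if not np.isin(self.pen, (0, 1)).all():
            raise ValueError("pen state must be 0 or 1")

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "pen": self.pen})


@dataclass
class AccelStream:
    """Tri-axial accelerometer series in g at a constant nominal rate."""

    t: np.ndarray
    axes: np.ndarray  # shape (n, 3)
    fs: float = ACCEL_FS
    wrist: str = "right"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[1] != 3:
            raise ValueError("axes must have shape (n, 3)")
        if len(self.t) != len(self.axes):
            raise ValueError("t and axes must have equal length")
        if not np.isfinite(self.axes).all():
            bad = int(np.flatnonzero(~np.isfinite(self.axes).all(axis=1))[0])
            raise ValueError(f"non-finite accelerometer sample at index {bad}")

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "ax": self.axes[:, 0], "ay": self.axes[:, 1], "az": self.axes[:, 2]}
        )

    def copy_with(self, **kw) -> "AccelStream":
        return replace(self, **kw)


def count_strict_peaks(x: np.ndarray) -> int:
    """Count strict interior local maxima: ``x[i-1] < x[i] > x[i+1]``.

    This is the fluency peak rule used for both tablet velocity profiles and
    accelerometer signals: neighbouring-value comparison with no amplitude
    threshold, and no credit for flat-topped plateaus.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return 0
    interior = x[1:-1]
    return int(np.sum((interior > x[:-2]) & (interior > x[2:])))
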