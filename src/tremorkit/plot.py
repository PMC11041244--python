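"""Quick-look plotting helpers for traces, velocity profiles, and spectra."""

from __future__ import annotations

import numpy as np

from .core import AccelStream, PenTrace
from .tablet_kinematics import segment_strokes, velocity_profiles


def plot_pen_trace(trace: PenTrace, ax=None):
    """Draw the pen path, one line per stroke."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stroke in segment_strokes(trace):
        ax.plot(stroke.x, stroke.y, lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{trace.task_id} {trace.condition}".strip())
    return ax


def plot_velocity_profile(trace: PenTrace, ax=None, **kw):
    """Overlay raw and smoothed pointwise velocity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    raw = velocity_profiles(trace, smooth=False, **kw)
    smooth = velocity_profiles(trace, smooth=True, **kw)
    offset = 0
    for vr, vs in zip(raw.v, smooth.v):
        t = (offset + np.arange(len(vr))) / raw.fs
        ax.plot(t, vr, color="0.7", lw=0.6)
        ax.plot(t[: len(vs)], vs, color="C0", lw=1.0)
        offset += len(vr) + int(0.2 * raw.fs)
    ax.set_xlabel("in-stroke time (s)")
    ax.set_ylabel("velocity (px/s)")
    return ax


def plot_accel_stream(stream: AccelStream, ax=None):
    """Plot the three acceleration axes against time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, lbl in enumerate("xyz"):
        ax.plot(stream.t, stream.axes[:, k], lw=0.5, label=f"a{lbl}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("acceleration (g)")
    ax.legend(loc="upper right")
    return ax
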