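"""Kinematic outcomes from digitized drawing and handwriting traces.

The processing chain reproduces the tablet analysis of the wrist-vibration
drawing protocol: stylus samples are segmented into strokes at pen lifts,
within-stroke pen displacement is converted to Euclidean distance traveled,
the distance series is resampled to a constant 142 Hz by linear
interpolation, pointwise velocity is the resampled distance increment over
the (now constant) sampling interval, and the velocity profile is smoothed
with a 3.5 Hz cutoff 5th-order low-pass Butterworth filter.  The six
outcomes are:

* ``duration`` — first stylus-down to last stylus-up, pauses included;
* ``pause_count`` / ``pause_time`` — number of stylus lifts between strokes
  and their summed duration;
* ``mean_velocity`` — mean of all in-stroke pointwise velocities (px/s);
* ``peak_count`` — fluency: strict local maxima of the smoothed velocity
  profile, counted by neighbouring-value comparison with no threshold;
* ``scaled_peaks`` — ``peak_count / duration`` (peaks/s).

All stages operate per stroke; stylus lifts contribute no velocity samples,
so no fictitious velocity spans a pen lift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import TABLET_FS, PenTrace, count_strict_peaks

__all__ = [
    "Stroke",
    "VelocityProfile",
    "TabletMetrics",
    "segment_strokes",
    "task_duration",
    "detect_pauses",
    "pointwise_distance",
    "resample_uniform",
    "pointwise_velocity",
    "smooth_velocity",
    "count_velocity_peaks",
    "mean_velocity",
    "velocity_profiles",
    "compute_tablet_metrics",
]

#: Strokes shorter than this many resampled points are left unsmoothed
#: (filter edge requirements) and the result flagged.
MIN_FILTER_SAMPLES = 18  # 3 * (order + 1) for the default 5th-order filter


@dataclass
class Stroke:
    """One maximal pen-down run."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VelocityProfile:
    """Per-stroke pointwise velocity series on a uniform grid."""

    fs: float
    v: list[np.ndarray]
    smoothed: bool = False
    cutoff: float | None = None
    order: int | None = None
    unsmoothed_strokes: list[int] = field(default_factory=list)

    def all_samples(self) -> np.ndarray:
        return np.concatenate(self.v) if self.v else np.empty(0)


@dataclass
class TabletMetrics:
    duration: float
    pause_count: int
    pause_time: float
    mean_velocity: float
    peak_count: int
    scaled_peaks: float
    n_strokes: int = 0
    n_unsmoothed_strokes: int = 0

    def as_dict(self) -> dict:
        return {
            "duration": self.duration,
            "pause_count": self.pause_count,
            "pause_time": self.pause_time,
            "mean_velocity": self.mean_velocity,
            "peak_count": self.peak_count,
            "scaled_peaks": self.scaled_peaks,
            "n_strokes": self.n_strokes,
            "n_unsmoothed_strokes": self.n_unsmoothed_strokes,
        }


def segment_strokes(trace: PenTrace) -> list[Stroke]:
    """Split a trace into maximal pen-down runs, in time order."""
    pen = np.asarray(trace.pen, dtype=bool)
    if not pen.any():
        raise ValueError("trace contains no pen-down sample")
    edges = np.diff(pen.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if pen[0]:
        starts.insert(0, 0)
    if pen[-1]:
        ends.append(len(pen))
    return [Stroke(trace.t[a:b], trace.x[a:b], trace.y[a:b]) for a, b in zip(starts, ends)]


def task_duration(strokes: list[Stroke]) -> float:
    """First stylus-down to last stylus-up, inter-stroke pauses included."""
    if not strokes:
        raise ValueError("no strokes")
    return float(strokes[-1].t[-1] - strokes[0].t[0])


def detect_pauses(strokes: list[Stroke]) -> tuple[int, float]:
    """Count stylus lifts between consecutive strokes and sum their durations."""
    if not strokes:
        raise ValueError("no strokes")
    gaps = []
    for prev, nxt in zip(strokes, strokes[1:]):
        gap = float(nxt.t[0] - prev.t[-1])
        if gap < 0:
            raise ValueError("strokes overlap in time")
        gaps.append(gap)
    return len(gaps), float(sum(gaps))


def pointwise_distance(stroke: Stroke) -> np.ndarray:
    """Euclidean displacement between consecutive samples (length n-1)."""
    if len(stroke) < 2:
        raise ValueError("stroke needs at least 2 samples for distances")
    return np.hypot(np.diff(stroke.x), np.diff(stroke.y))


def resample_uniform(t: np.ndarray, values: np.ndarray, fs: float = TABLET_FS) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate ``values`` onto a uniform grid anchored at ``t[0]``.

    The grid spans the input without extrapolating beyond the last timestamp.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing with >= 2 points")
    n = int(np.floor((t[-1] - t[0]) * fs + 1e-9)) + 1
    grid = t[0] + np.arange(n) / fs
    return grid, np.interp(grid, t, values)


def pointwise_velocity(distances: np.ndarray, intervals: np.ndarray | float) -> np.ndarray:
    """v_i = d_i / dt_i in pixels/second."""
    distances = np.asarray(distances, dtype=float)
    intervals = np.broadcast_to(np.asarray(intervals, dtype=float), distances.shape)
    if np.any(intervals <= 0):
        raise ValueError("time intervals must be positive")
    return distances / intervals


def smooth_velocity(
    v: np.ndarray,
    fs: float = TABLET_FS,
    cutoff: float = 3.5,
    order: int = 5,
    zero_phase: bool = False,
) -> np.ndarray:
    """Low-pass Butterworth smoothing of one stroke's velocity series.

    Default is a single forward pass (initialized at the signal's first
    value, so a constant series passes through unchanged); ``zero_phase``
    switches to forward-backward filtering, squaring the magnitude response
    and cancelling phase delay.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < MIN_FILTER_SAMPLES:
        raise ValueError(
            f"stroke too short to filter: {len(v)} < {MIN_FILTER_SAMPLES} samples"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    if zero_phase:
        return signal.filtfilt(b, a, v)
    zi = signal.lfilter_zi(b, a) * v[0]
    out, _ = signal.lfilter(b, a, v, zi=zi)
    return out


def count_velocity_peaks(profile: VelocityProfile, duration: float) -> tuple[int, float]:
    """Fluency: strict local maxima summed across strokes, and peaks/second."""
    peaks = sum(count_strict_peaks(v) for v in profile.v)
    return peaks, peaks / duration if duration > 0 else float("nan")


def mean_velocity(profile: VelocityProfile) -> float:
    """Arithmetic mean over all in-stroke velocity samples."""
    samples = profile.all_samples()
    if len(samples) == 0:
        raise ValueError("no velocity samples")
    return float(np.mean(samples))


def velocity_profiles(
    trace: PenTrace,
    fs: float = TABLET_FS,
    cutoff: float = 3.5,
    order: int = 5,
    zero_phase: bool = False,
    smooth: bool = True,
) -> VelocityProfile:
    """Run segment -> distance -> resample -> velocity (-> smooth) per stroke.

    Strokes too short to resample (< 2 grid points) are skipped; strokes too
    short to filter keep their raw velocity and are flagged in
    ``unsmoothed_strokes``.
    """
    strokes = segment_strokes(trace)
    vs: list[np.ndarray] = []
    unsmoothed: list[int] = []
    for i, stroke in enumerate(strokes):
        if len(stroke) < 2:
            unsmoothed.append(i)
            continue
        d = pointwise_distance(stroke)
        cumdist = np.concatenate([[0.0], np.cumsum(d)])
        _, c = resample_uniform(stroke.t, cumdist, fs=fs)
        if len(c) < 2:
            unsmoothed.append(i)
            continue
        v = pointwise_velocity(np.diff(c), 1.0 / fs)
        if smooth:
            if len(v) >= MIN_FILTER_SAMPLES:
                v = smooth_velocity(v, fs=fs, cutoff=cutoff, order=order, zero_phase=zero_phase)
            else:
                unsmoothed.append(i)
                warnings.warn(
                    f"stroke {i} too short to smooth ({len(v)} samples); using raw velocity",
                    stacklevel=2,
                )
        vs.append(v)
    return VelocityProfile(
        fs=fs,
        v=vs,
        smoothed=smooth,
        cutoff=cutoff if smooth else None,
        order=order if smooth else None,
        unsmoothed_strokes=unsmoothed,
    )


def compute_tablet_metrics(
    trace: PenTrace,
    fs: float = TABLET_FS,
    cutoff: float = 3.5,
    order: int = 5,
    zero_phase: bool = False,
) -> TabletMetrics:
    """Compute the six drawing outcomes for one task repetition."""
    strokes = segment_strokes(trace)
    dur = task_duration(strokes)
    pause_count, pause_time = detect_pauses(strokes)
    profile = velocity_profiles(trace, fs=fs, cutoff=cutoff, order=order, zero_phase=zero_phase)
    if profile.v:
        mv = mean_velocity(profile)
        peaks, scaled = count_velocity_peaks(profile, dur)
    else:
        mv, peaks, scaled = float("nan"), 0, float("nan")
    return TabletMetrics(
        duration=dur,
        pause_count=pause_count,
        pause_time=pause_time,
        mean_velocity=mv,
        peak_count=peaks,
        scaled_peaks=scaled,
        n_strokes=len(strokes),
        n_unsmoothed_strokes=len(profile.unsmoothed_strokes),
    )
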