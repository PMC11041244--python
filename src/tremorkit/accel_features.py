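"""Feature extraction from 128 Hz wrist accelerometry.

The stream is synchronized to the task via clap bursts (power threshold 0.17
sustained for 110 consecutive samples), low-pass filtered with a zero-phase
3.5 Hz 5th-order Butterworth, differentiated to jerk, and summarized by 32
per-axis metrics for both the acceleration and jerk signals:

mean, Hjorth mobility and complexity, roughness (sum of squared second
differences), rugosity (RMS of first differences), normalized Shannon
spectral entropy, mean frequency, the energy in twenty-four consecutive
0.5 Hz bands starting at 2 Hz, and fluency (normalized peak count, sharing
the tablet peak rule).

The spectral quantities are computed on the *raw* segment by default —
band energies up to 12 Hz are uninformative after a 3.5 Hz low-pass — while
the time-domain metrics use the filtered signal; ``literal_filtering=True``
computes everything on the filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import AccelStream, count_strict_peaks

__all__ = [
    "ClapEvent",
    "JerkStream",
    "lowpass_zero_phase",
    "detect_claps",
    "segment_by_clap",
    "compute_jerk",
    "hjorth_mobility",
    "hjorth_complexity",
    "roughness",
    "rugosity",
    "spectral_features",
    "signal_fluency",
    "compute_signal_features",
    "feature_columns",
    "BAND_EDGES",
]

AXES = ("x", "y", "z")
#: Edges of the twenty-four 0.5 Hz energy bands, starting at 2 Hz.
BAND_EDGES = 2.0 + 0.5 * np.arange(25)
#: filtfilt needs len > 3 * (filter order); minimum usable segment length.
MIN_FILTER_LEN = 16


@dataclass
class ClapEvent:
    start_index: int
    start_time: float
    run_length: int


@dataclass
class JerkStream:
    """First-difference derivative of acceleration, in g/s (length n-1)."""

    t: np.ndarray
    axes: np.ndarray
    fs: float


def lowpass_zero_phase(
    stream: AccelStream, cutoff: float = 3.5, order: int = 5
) -> AccelStream:
    """Zero-phase (forward-backward) low-pass Butterworth, per axis.

    The effective magnitude response is the squared single-pass response and
    the phase shift is zero.
    """
    if len(stream) < MIN_FILTER_LEN:
        raise ValueError(
            f"stream too short for zero-phase filtering: {len(stream)} < {MIN_FILTER_LEN}"
        )
    b, a = sps.butter(order, cutoff, btype="low", fs=stream.fs)
    out = np.column_stack([sps.filtfilt(b, a, stream.axes[:, k]) for k in range(3)])
    return stream.copy_with(axes=out, filtered=True)


def clap_power_series(stream: AccelStream) -> np.ndarray:
    """Squared magnitude of the mean-removed 3-axis vector, in g^2."""
    centered = stream.axes - stream.axes.mean(axis=0, keepdims=True)
    return np.sum(centered**2, axis=1)


def detect_claps(
    stream: AccelStream, power_threshold: float = 0.17, min_run: int = 110
) -> list[ClapEvent]:
    """Find clap bursts in a raw stream.

    An event starts at the first sample of a maximal run of at least
    ``min_run`` consecutive samples whose power meets ``power_threshold``
    (the start sample counts toward the run).
    """
    power = clap_power_series(stream)
    above = power >= power_threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    events = []
    for a, b in zip(starts, ends):
        if b - a >= min_run:
            events.append(ClapEvent(start_index=int(a), start_time=float(stream.t[a]), run_length=int(b - a)))
    return events


def segment_by_clap(
    stream: AccelStream,
    clap: ClapEvent,
    task_window: float | None = None,
    offset: float = 1.0,
) -> AccelStream:
    """Extract the task segment that follows a synchronization clap.

    The segment starts ``offset`` seconds after the clap's last sample and
    lasts ``task_window`` seconds (to the end of the stream when ``None``).
    A window running past the stream end is truncated with a warning.
    """
    import warnings

    start_t = stream.t[clap.start_index] + clap.run_length / stream.fs + offset
    i0 = int(np.searchsorted(stream.t, start_t - 1e-9))
    if i0 >= len(stream):
        raise ValueError("segment start lies past the end of the stream")
    if task_window is None:
        i1 = len(stream)
    else:
        i1 = i0 + int(round(task_window * stream.fs))
        if i1 > len(stream):
            warnings.warn("task window exceeds stream end; truncating", stacklevel=2)
            i1 = len(stream)
    return stream.copy_with(t=stream.t[i0:i1], axes=stream.axes[i0:i1])


def compute_jerk(stream: AccelStream) -> JerkStream:
    """j_i = (a_{i+1} - a_i) * fs, per axis, in g/s."""
    if len(stream) < 2:
        raise ValueError("need >= 2 samples to differentiate")
    return JerkStream(
        t=stream.t[:-1], axes=np.diff(stream.axes, axis=0) * stream.fs, fs=stream.fs
    )


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def hjorth_mobility(x: np.ndarray, fs: float) -> float:
    """sqrt(var(dx/dt) / var(x)), derivative by first difference times fs.

    For a pure sinusoid at frequency f this equals
    2*pi*f * sinc-correction ~= 2*pi*f (units 1/s).  Undefined (NaN) for a
    zero-variance signal.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples")
    vx = np.var(x)
    if vx <= 0:
        return float("nan")
    return float(np.sqrt(np.var(np.diff(x) * fs) / vx))


def hjorth_complexity(x: np.ndarray, fs: float) -> float:
    """mobility(dx/dt) / mobility(x); 1 for a pure sinusoid, > 1 for noise."""
    x = np.asarray(x, dtype=float)
    m = hjorth_mobility(x, fs)
    if not np.isfinite(m) or m == 0:
        return float("nan")
    md = hjorth_mobility(np.diff(x) * fs, fs)
    if not np.isfinite(md):
        return float("nan")
    return float(md / m)


def roughness(x: np.ndarray) -> float:
    """Curvature energy: sum of squared second differences."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples")
    return float(np.sum(np.diff(x, n=2) ** 2))


def rugosity(x: np.ndarray) -> float:
    """Small-scale variability: RMS of first differences."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def spectral_features(
    x: np.ndarray, fs: float, normalize_entropy: bool = True
) -> tuple[float, float, np.ndarray]:
    """(entropy, mean_frequency, band_energy[24]) from a Hann periodogram.

    The mean-removed signal's single-segment Hann periodogram defines a
    probability distribution p(f) over the positive-frequency bins; entropy
    is Shannon entropy of p, normalized by log(number of bins) to land in
    [0, 1]; mean frequency is sum f * p(f); band energies sum raw periodogram
    power inside each of the 24 half-Hz bands starting at 2 Hz.  Requires
    >= 4 s of signal so each band spans at least two bins.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * fs:
        raise ValueError("spectral features need a segment of at least 4 seconds")
    freqs, power = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = power.sum()
    if total <= 0:
        return float("nan"), float("nan"), np.full(len(BAND_EDGES) - 1, np.nan)
    p = power / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    if normalize_entropy:
        entropy /= np.log(len(p))
    mean_freq = float((freqs * p).sum())
    band_energy = np.array(
        [
            power[(freqs >= lo) & (freqs < hi)].sum()
            for lo, hi in zip(BAND_EDGES[:-1], BAND_EDGES[1:])
        ]
    )
    return entropy, mean_freq, band_energy


def signal_fluency(x: np.ndarray, duration: float) -> tuple[int, float]:
    """Strict local-maxima count and peaks/second (same rule as the tablet)."""
    peaks = count_strict_peaks(x)
    return peaks, peaks / duration if duration > 0 else float("nan")


# ---------------------------------------------------------------------------
# Per-segment feature vectors
# ---------------------------------------------------------------------------

_SCALAR_FEATURES = ("mean", "mobility", "complexity", "roughness", "rugosity",
                    "entropy", "mean_frequency")
_BAND_NAMES = tuple(
    f"band_{lo:.1f}_{hi:.1f}" for lo, hi in zip(BAND_EDGES[:-1], BAND_EDGES[1:])
)
#: The 32 canonical per-axis features (normalized_peaks is the fluency metric).
FEATURE_NAMES = _SCALAR_FEATURES + _BAND_NAMES + ("normalized_peaks",)


def feature_columns() -> list[str]:
    """Column names of the wide feature table: ``sig_axis_feature``."""
    cols = []
    for sig in ("acc", "jerk"):
        for ax in AXES:
            for f in FEATURE_NAMES + ("peaks",):
                cols.append(f"{sig}_{ax}_{f}")
    return cols


def _featurize_axis(
    x_time: np.ndarray, x_spec: np.ndarray, fs: float, duration: float
) -> dict[str, float]:
    out: dict[str, float] = {}
    out["mean"] = float(np.mean(x_time))
    out["mobility"] = hjorth_mobility(x_time, fs)
    out["complexity"] = hjorth_complexity(x_time, fs)
    out["roughness"] = roughness(x_time)
    out["rugosity"] = rugosity(x_time)
    try:
        ent, mf, bands = spectral_features(x_spec, fs)
    except ValueError:
        ent, mf = float("nan"), float("nan")
        bands = np.full(len(_BAND_NAMES), np.nan)
    out["entropy"] = ent
    out["mean_frequency"] = mf
    for name, e in zip(_BAND_NAMES, bands):
        out[name] = float(e)
    peaks, norm = signal_fluency(x_time, duration)
    out["peaks"] = peaks
    out["normalized_peaks"] = norm
    return out


def compute_signal_features(
    segment: AccelStream,
    cutoff: float = 3.5,
    order: int = 5,
    literal_filtering: bool = False,
) -> dict[str, float]:
    """32 features per axis for acceleration and jerk of one task segment.

    ``segment`` is the raw task window.  Time-domain features use the
    zero-phase-filtered signal; spectral features use the raw segment unless
    ``literal_filtering`` is set.  Returns a flat dict keyed
    ``{acc|jerk}_{x|y|z}_{feature}`` (192 canonical scalars plus the two
    raw ``peaks`` counts per signal-axis as bookkeeping columns).
    """
    filtered = lowpass_zero_phase(segment, cutoff=cutoff, order=order)
    duration = (len(segment) - 1) / segment.fs
    jerk_f = compute_jerk(filtered)
    jerk_r = compute_jerk(segment)
    spec_acc = filtered if literal_filtering else segment
    spec_jerk = jerk_f if literal_filtering else jerk_r
    out: dict[str, float] = {}
    for k, ax in enumerate(AXES):
        for name, val in _featurize_axis(
            filtered.axes[:, k], spec_acc.axes[:, k], segment.fs, duration
        ).items():
            out[f"acc_{ax}_{name}"] = val
        for name, val in _featurize_axis(
            jerk_f.axes[:, k], spec_jerk.axes[:, k], segment.fs, duration
        ).items():
            out[f"jerk_{ax}_{name}"] = val
    return out
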