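"""Shared fixtures: constructed pen traces with hand-computable outcomes."""

from __future__ import annotations

import numpy as np
import pytest

from tremorkit.core import PenTrace


def brute_force_peaks(x) -> int:
    """Independent strict-local-maximum count by explicit iteration."""
    x = list(map(float, x))
    count = 0
    for i in range(1, len(x) - 1):
        if x[i - 1] < x[i] and x[i] > x[i + 1]:
            count += 1
    return count


def make_wavy_trace(
    n_strokes: int = 2,
    stroke_duration: float = 4.0,
    speed: float = 120.0,
    amp_frac: float = 0.3,
    wave_freq: float = 1.0,
    pause: float = 0.5,
    fs: float = 142.0,
) -> tuple[PenTrace, dict]:
    """A trace whose outcomes are all computable by construction.

    Each stroke moves along +x with speed v(tau) = speed * (1 + amp_frac *
    sin(2*pi*wave_freq*tau)) (position obtained by exact integration),
    sampled exactly at ``fs``; ``wave_freq * stroke_duration`` must be an
    integer so each stroke contributes exactly that many velocity maxima and
    a mean speed of ``speed``.  Pen-up hover samples mark the lifts.
    Returns the trace and the expected metric values.
    """
    n_cycles = wave_freq * stroke_duration
    assert abs(n_cycles - round(n_cycles)) < 1e-9, "need integer wave cycles per stroke"
    T, X, Y, P = [], [], [], []
    t0, x0 = 0.0, 0.0
    for s in range(n_strokes):
        n = int(round(stroke_duration * fs)) + 1
        t = t0 + np.arange(n) / fs
        tau = t - t0
        x = x0 + speed * (
            tau + amp_frac / (2 * np.pi * wave_freq) * (1 - np.cos(2 * np.pi * wave_freq * tau))
        )
        T.append(t)
        X.append(x)
        Y.append(np.zeros(n))
        P.append(np.ones(n, dtype=int))
        if s + 1 < n_strokes:
            gap = np.linspace(t[-1], t[-1] + pause, 4)[1:-1]
            T.append(gap)
            X.append(np.full(2, x[-1]))
            Y.append(np.zeros(2))
            P.append(np.zeros(2, dtype=int))
        t0 = t[-1] + pause
        x0 = x[-1] + 5.0
    trace = PenTrace(
        t=np.concatenate(T), x=np.concatenate(X), y=np.concatenate(Y), pen=np.concatenate(P)
    )
    expected = {
        "duration": n_strokes * stroke_duration + (n_strokes - 1) * pause,
        "pause_count": n_strokes - 1,
        "pause_time": (n_strokes - 1) * pause,
        "mean_velocity": speed,
        "peak_count": n_strokes * int(round(n_cycles)),
    }
    return trace, expected


@pytest.fixture
def wavy_trace():
    return make_wavy_trace
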