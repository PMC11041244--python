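"""Synthetic pen traces, wrist accelerometry, and cohorts for tremor analysis.

No public recordings exist for the wrist-vibration drawing study this package
analyses, so every downstream stage is exercised on simulated data whose
generating parameters are known exactly.  The simulator emulates:

* the five drawing/writing tasks (rectangle, Archimedean spiral, 10-vertex
  star, a cursive "elelelel" loop chain, and a multi-word printed sentence),
  traversed at constant base speed with stylus lifts between strokes;
* action tremor as an additive sinusoid (default 6.5 Hz, the ~4-6 Hz
  Parkinsonian rest-tremor band shifted up ~1.5 Hz) applied normal to the
  pen path, and as a tri-axial sinusoid in the accelerometer;
* tablet sampling at a nominal 142 Hz with Gaussian inter-sample jitter;
* 128 Hz accelerometry containing voluntary low-frequency movement (< 2 Hz),
  the tremor oscillation, white noise, and clap bursts used downstream for
  stream/task synchronization;
* three vibration conditions (none / low / high) whose effect enters only as
  a configurable multiplier on tremor amplitude, plus per-participant random
  intercepts — the statistical structure the mixed-model stage assumes.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .core import ACCEL_FS, CONDITIONS, TABLET_FS, TASKS, AccelStream, PenTrace

__all__ = [
    "TaskSpec",
    "TremorSpec",
    "ConditionSpec",
    "ClapSpec",
    "VoluntarySpec",
    "CohortSpec",
    "Trajectory",
    "generate_task_path",
    "time_parameterize",
    "add_tremor",
    "sample_pen_trace",
    "generate_accel_stream",
    "generate_cohort",
    "simulate_trial_outcomes",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """Geometry and pacing of one drawing task.

    ``size_px`` sets the overall scale (rectangle width, spiral/star outer
    radius, loop-chain span, sentence width).  ``base_speed`` is the constant
    pen speed along the ideal path in pixels/second; ``inter_stroke_pause``
    is the stylus-lift duration inserted between strokes.
    """

    task_id: str
    size_px: float = 300.0
    turns: int = 3  # spiral
    star_points: int = 5  # -> 2*points vertices, alternating radius
    loops: int = 4  # elelelel
    word_count: int = 5  # handwriting (one stroke per word)
    base_speed: float = 150.0
    inter_stroke_pause: float = 0.5
    rectangle_closed: bool = True

    def __post_init__(self) -> None:
        if self.task_id not in TASKS:
            raise ValueError(f"unknown task_id {self.task_id!r}; expected one of {TASKS}")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")
        if self.inter_stroke_pause < 0:
            raise ValueError("inter_stroke_pause must be nonnegative")
        for name in ("size_px", "turns", "star_points", "loops", "word_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.task_id == "handwriting" and self.word_count < 2:
            raise ValueError("handwriting needs word_count >= 2 so that pauses occur")


@dataclass
class TremorSpec:
    """Oscillatory tremor parameters shared by the pen and accel simulators.

    ``amplitude_px`` is the peak pen-space displacement normal to the path;
    ``amplitude_g`` the peak acceleration of the wrist oscillation.
    ``amplitude_jitter`` modulates the amplitude slowly (fractional SD).
    """

    frequency: float = 6.5
    amplitude_px: float = 4.0
    amplitude_g: float = 0.15
    phase: float = 0.0
    amplitude_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.frequency < ACCEL_FS / 2:
            raise ValueError("frequency must lie in (0, 64) Hz")
        if self.amplitude_px < 0 or self.amplitude_g < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not 0 <= self.amplitude_jitter < 1:
            raise ValueError("amplitude_jitter must lie in [0, 1)")


@dataclass
class ConditionSpec:
    """One vibration condition and its simulated effect.

    ``effect`` multiplies the tremor amplitude for repetitions recorded under
    this condition; 1.0 embeds the null (no condition effect).
    """

    condition: str
    effect: float = 1.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.effect <= 0:
            raise ValueError("effect factor must be positive")


@dataclass
class ClapSpec:
    """Synchronization clap bursts preceding the task window."""

    clap_times: tuple[float, ...] = (1.0,)
    clap_duration_samples: int = 120
    clap_power: float = 0.3

    def __post_init__(self) -> None:
        if self.clap_power <= 0.17:
            raise ValueError("clap_power must exceed the 0.17 detection threshold")
        if self.clap_duration_samples < 110:
            raise ValueError("clap_duration_samples must be >= 110 to be detectable")
        if any(t < 0 for t in self.clap_times):
            raise ValueError("clap times must be nonnegative")


@dataclass
class VoluntarySpec:
    """Voluntary (non-tremor) wrist movement: sum of sub-2 Hz sinusoids."""

    n_components: int = 3
    freq_range: tuple[float, float] = (0.2, 1.8)
    amplitude_g: float = 0.05

    def __post_init__(self) -> None:
        if self.freq_range[1] >= 2.0:
            raise ValueError("voluntary movement must stay below 2 Hz")


@dataclass
class CohortSpec:
    """A full simulated cohort: participants x tasks x conditions.

    Defaults mirror the pilot-study design: 9 participants, the 5 drawing
    tasks, 3 counterbalanced vibration intensities, one analysed repetition
    per cell, and no condition effect (the study's result was null).
    ``intercept_sd`` perturbs each participant's tremor amplitude (pixels);
    ``residual_sd`` adds repetition-level amplitude noise.
    """

    n_participants: int = 9
    tasks: tuple[TaskSpec, ...] = field(
        default_factory=lambda: tuple(TaskSpec(t) for t in TASKS)
    )
    conditions: tuple[ConditionSpec, ...] = field(
        default_factory=lambda: tuple(ConditionSpec(c, 1.0) for c in CONDITIONS)
    )
    repetitions: int = 1
    tremor: TremorSpec = field(default_factory=TremorSpec)
    intercept_sd: float = 1.0
    residual_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if len(self.conditions) != len(CONDITIONS):
            raise ValueError("exactly three conditions per participant-task")


# ---------------------------------------------------------------------------
# Ideal task geometry
# ---------------------------------------------------------------------------

def _resample_polyline(xy: np.ndarray, spacing: float) -> np.ndarray:
    """Re-interpolate a polyline to ~uniform arc-length spacing."""
    xy = np.asarray(xy, dtype=float)
    d = np.hypot(*np.diff(xy, axis=0).T)
    keep = np.concatenate([[True], d > 0])
    xy = xy[keep]
    if len(xy) < 2:
        raise ValueError("degenerate stroke: zero total arc length")
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))])
    n = max(int(np.ceil(s[-1] / spacing)), 2)
    grid = np.linspace(0.0, s[-1], n + 1)
    return np.column_stack([np.interp(grid, s, xy[:, 0]), np.interp(grid, s, xy[:, 1])])


def arc_length(stroke: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(np.asarray(stroke, float), axis=0).T)))


def spiral_arc_length(b: float, theta_max: float) -> float:
    """Closed-form check value for the Archimedean spiral r = b*theta."""
    val, _ = integrate.quad(lambda th: b * np.sqrt(1.0 + th * th), 0.0, theta_max)
    return val


def generate_task_path(spec: TaskSpec, seed: int = 0, spacing: float = 0.5) -> list[np.ndarray]:
    """Return the ideal pen path as per-stroke (n, 2) arrays.

    Strokes are arc-length parameterized polylines (uniform spacing
    ``spacing`` pixels).  The geometry is deliberately schematic: the
    downstream metrics depend on timing and stroke structure, not on
    glyph-accurate shapes.
    """
    rng = np.random.default_rng(seed)
    t = spec.task_id
    if t == "rectangle":
        w, h = spec.size_px, spec.size_px / 2.0
        corners = np.array([[0, 0], [w, 0], [w, h], [0, h], [0, 0]], dtype=float)
        if spec.rectangle_closed:
            strokes = [corners]
        else:
            strokes = [corners[i : i + 2].copy() for i in range(4)]
    elif t == "spiral":
        theta_max = 2.0 * np.pi * spec.turns
        b = spec.size_px / theta_max
        theta = np.linspace(0.0, theta_max, 20000)
        r = b * theta
        strokes = [np.column_stack([r * np.cos(theta), r * np.sin(theta)])]
    elif t == "star":
        k = 2 * spec.star_points
        ang = -np.pi / 2 + 2.0 * np.pi * np.arange(k + 1) / k
        rad = np.where(np.arange(k + 1) % 2 == 0, spec.size_px, 0.45 * spec.size_px)
        strokes = [np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])]
    elif t == "elelelel":
        # prolate cycloid: loops when the rolling radius exceeds the advance
        s = np.linspace(0.0, 2.0 * np.pi * spec.loops, 4000 * spec.loops)
        c = spec.size_px / (2.0 * np.pi * spec.loops)
        r = 1.8 * c
        strokes = [np.column_stack([c * s - r * np.sin(s), r * np.cos(s)])]
    elif t == "handwriting":
        # one smooth pseudo-random stroke per word, advancing left to right
        strokes = []
        word_w = spec.size_px / spec.word_count
        for w_i in range(spec.word_count):
            u = np.linspace(0.0, 1.0, 400)
            x = w_i * 1.2 * word_w + word_w * u
            y = np.zeros_like(u)
            for j in (1, 2, 3):  # < 3 "cycles per word": smooth, low frequency
                y += rng.uniform(0.1, 0.3) * word_w * np.sin(
                    2.0 * np.pi * j * u + rng.uniform(0, 2 * np.pi)
                )
            strokes.append(np.column_stack([x, y]))
    else:  # pragma: no cover - guarded by TaskSpec
        raise ValueError(t)
    out = [_resample_polyline(s, spacing) for s in strokes]
    if not all(np.isfinite(s).all() for s in out):
        raise ValueError("non-finite vertex in generated path")
    return out


# ---------------------------------------------------------------------------
# Time parameterization and tremor
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-parameterized pen trajectory: per-stroke (t, x, y) at fine dt."""

    strokes: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    base_speed: float

    @property
    def duration(self) -> float:
        return float(self.strokes[-1][0][-1] - self.strokes[0][0][0])


def time_parameterize(
    path: list[np.ndarray],
    base_speed: float,
    inter_stroke_pause: float = 0.5,
    dt: float = 1e-3,
    t_start: float = 0.0,
) -> Trajectory:
    """Traverse each stroke at constant ``base_speed``, inserting lifts.

    Returns a dense (``dt``-spaced) trajectory suitable for tremor injection
    and jittered resampling.
    """
    if base_speed <= 0:
        raise ValueError("base_speed must be positive")
    strokes = []
    t0 = t_start
    for xy in path:
        xy = np.asarray(xy, dtype=float)
        seg = np.hypot(*np.diff(xy, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            raise ValueError("stroke with zero arc length cannot be time-parameterized")
        dur = s[-1] / base_speed
        t = t0 + np.arange(0.0, dur + dt / 2, dt)
        s_t = np.clip((t - t0) * base_speed, 0.0, s[-1])
        strokes.append((t, np.interp(s_t, s, xy[:, 0]), np.interp(s_t, s, xy[:, 1])))
        t0 = t[-1] + inter_stroke_pause
    return Trajectory(strokes=strokes, base_speed=base_speed)


def add_tremor(traj: Trajectory, tremor: TremorSpec, seed: int = 0) -> Trajectory:
    """Superimpose tremor normal to the local path tangent.

    p'(t) = p(t) + A(t) sin(2*pi*f*t + phi) * n(t), with n the unit normal.
    A zero amplitude returns the trajectory unchanged.  Tangents at repeated
    points are filled from the nearest moving sample.
    """
    if tremor.amplitude_px == 0.0:
        return Trajectory([s for s in traj.strokes], traj.base_speed)
    rng = np.random.default_rng(seed)
    out = []
    for t, x, y in traj.strokes:
        if len(t) < 2:
            raise ValueError("stroke collapsed to a single point; tangent undefined")
        dx, dy = np.gradient(x, t), np.gradient(y, t)
        norm = np.hypot(dx, dy)
        ok = norm > 1e-12
        if not ok.any():
            raise ValueError("entire stroke is stationary; tangent undefined")
        # interpolate tangents across momentary stalls
        idx = np.arange(len(t))
        dx = np.interp(idx, idx[ok], dx[ok])
        dy = np.interp(idx, idx[ok], dy[ok])
        norm = np.hypot(dx, dy)
        nx, ny = -dy / norm, dx / norm
        amp = tremor.amplitude_px * np.ones_like(t)
        if tremor.amplitude_jitter > 0:
            # slow (~0.5 Hz) seeded amplitude modulation, clipped nonnegative
            f_m = 0.5
            mod = rng.normal(0.0, tremor.amplitude_jitter) * np.sin(
                2.0 * np.pi * f_m * t + rng.uniform(0, 2 * np.pi)
            )
            amp = np.clip(amp * (1.0 + mod), 0.0, None)
        disp = amp * np.sin(2.0 * np.pi * tremor.frequency * t + tremor.phase)
        out.append((t, x + disp * nx, y + disp * ny))
    return Trajectory(out, traj.base_speed)


def sample_pen_trace(
    traj: Trajectory,
    target_fs: float = TABLET_FS,
    jitter_sd: float = 0.0,
    seed: int = 0,
    hover_samples: int = 2,
    **meta,
) -> PenTrace:
    """Sample a trajectory the way the tablet does.

    Inter-sample intervals are 1/``target_fs`` plus Gaussian jitter
    (``jitter_sd`` seconds), clamped to stay positive so timestamps remain
    strictly increasing.  ``hover_samples`` pen-up samples are emitted inside
    each lift (the stylus hovering at the lift-off position), which is how
    pauses appear in the recorded file.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    dt0 = 1.0 / target_fs
    min_dt = 0.2 * dt0
    clamped = False
    rows_t, rows_x, rows_y, rows_p = [], [], [], []
    for k, (t, x, y) in enumerate(traj.strokes):
        ts = [t[0]]
        while True:
            step = dt0 + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
            if step < min_dt:
                step = min_dt
                clamped = True
            nxt = ts[-1] + step
            if nxt > t[-1] + 1e-12:
                break
            ts.append(nxt)
        ts = np.asarray(ts)
        rows_t.append(ts)
        rows_x.append(np.interp(ts, t, x))
        rows_y.append(np.interp(ts, t, y))
        rows_p.append(np.ones(len(ts), dtype=int))
        t_next = traj.strokes[k + 1][0][0] if k + 1 < len(traj.strokes) else None
        if t_next is not None and hover_samples > 0 and t_next - ts[-1] > 3 * min_dt:
            gap = np.linspace(ts[-1], t_next, hover_samples + 2)[1:-1]
            rows_t.append(gap)
            rows_x.append(np.full(len(gap), rows_x[-1][-1]))
            rows_y.append(np.full(len(gap), rows_y[-1][-1]))
            rows_p.append(np.zeros(len(gap), dtype=int))
    if clamped:
        warnings.warn("sampling jitter clamped to keep timestamps increasing", stacklevel=2)
    return PenTrace(
        t=np.concatenate(rows_t),
        x=np.concatenate(rows_x),
        y=np.concatenate(rows_y),
        pen=np.concatenate(rows_p),
        **meta,
    )


# ---------------------------------------------------------------------------
# Accelerometry
# ---------------------------------------------------------------------------

#: Unit-norm distribution of the tremor oscillation across sensor axes.
TREMOR_AXIS_WEIGHTS = np.array([0.72, 0.55, 0.42])
TREMOR_AXIS_WEIGHTS = TREMOR_AXIS_WEIGHTS / np.linalg.norm(TREMOR_AXIS_WEIGHTS)


def generate_accel_stream(
    duration: float,
    tremor: TremorSpec,
    claps: ClapSpec | None = None,
    voluntary: VoluntarySpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    task_onset: float = 0.0,
    fs: float = ACCEL_FS,
    wrist: str = "right",
) -> AccelStream:
    """Simulate one wrist accelerometer recording.

    From ``task_onset`` onward the stream carries voluntary movement (a sum
    of sub-2 Hz sinusoids), the tremor sinusoid distributed across axes with
    unit-norm weights, and white Gaussian noise.  Clap bursts — square
    envelopes of alternating-sign samples whose vector-norm power stays at
    ``clap_power`` — are inserted at ``clap_times`` and must end before the
    task onset.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    axes = np.zeros((n, 3))
    active = t >= task_onset
    if voluntary is not None:
        for _ in range(voluntary.n_components):
            f = rng.uniform(*voluntary.freq_range)
            ph = rng.uniform(0, 2 * np.pi)
            w = rng.dirichlet(np.ones(3))
            axes += np.outer(
                active * voluntary.amplitude_g * np.sin(2 * np.pi * f * t + ph), w
            )
    if tremor.amplitude_g > 0:
        osc = tremor.amplitude_g * np.sin(2 * np.pi * tremor.frequency * t + tremor.phase)
        axes += np.outer(active * osc, TREMOR_AXIS_WEIGHTS)
    if noise_sd > 0:
        axes += rng.normal(0.0, noise_sd, size=axes.shape)
    if claps is not None:
        for ct in claps.clap_times:
            i0 = int(round(ct * fs))
            i1 = i0 + claps.clap_duration_samples
            if i1 > n:
                raise ValueError("clap extends past the end of the stream")
            if i1 / fs > task_onset:
                raise ValueError(
                    f"clap ending at {i1 / fs:.3f}s overlaps the task window "
                    f"(onset {task_onset:.3f}s); claps must precede task onset"
                )
            m = claps.clap_duration_samples
            # alternating-sign burst assigned (not added) on x so the vector
            # power is guaranteed >= clap_power at every burst sample
            sign = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
            mag = np.sqrt(claps.clap_power) * (1.05 + rng.uniform(0.0, 0.4, size=m))
            axes[i0:i1, 0] = sign * mag
    return AccelStream(t=t, axes=axes, fs=fs, wrist=wrist)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, out_dir) -> "pd.DataFrame":
    """Write a full simulated cohort to ``out_dir``; return the manifest.

    One pen trace and one accelerometer stream per participant x task x
    condition x repetition.  Participant random intercepts (N(0,
    ``intercept_sd``), pixels) and repetition noise perturb the pen tremor
    amplitude additively; condition effects multiply it.  The accel tremor
    amplitude is scaled by the same relative factor.  Ground truth is written
    alongside for recovery tests.  Deterministic for a fixed seed.
    """
    import pandas as pd

    from .io import write_accel_stream, write_pen_trace

    from pathlib import Path

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "traces").mkdir(exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    root = np.random.SeedSequence(spec.seed)
    intercepts = np.random.default_rng(root.spawn(1)[0]).normal(
        0.0, spec.intercept_sd, spec.n_participants
    )
    claps = ClapSpec()
    sync_offset = 1.0
    rows, truth = [], []
    idx = 0
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        for task in spec.tasks:
            for cond in spec.conditions:
                for rep in range(1, spec.repetitions + 1):
                    ss = np.random.SeedSequence([spec.seed, 1000 + idx])
                    rng = np.random.default_rng(ss)
                    s_path, s_trem, s_pen, s_acc = rng.integers(0, 2**31 - 1, 4)
                    amp_px = max(
                        0.0,
                        spec.tremor.amplitude_px * cond.effect
                        + intercepts[p]
                        + rng.normal(0.0, spec.residual_sd),
                    )
                    rel = amp_px / spec.tremor.amplitude_px if spec.tremor.amplitude_px else 0.0
                    amp_g = spec.tremor.amplitude_g * rel
                    trem = TremorSpec(
                        frequency=spec.tremor.frequency,
                        amplitude_px=amp_px,
                        amplitude_g=amp_g,
                        phase=rng.uniform(0, 2 * np.pi),
                        amplitude_jitter=spec.tremor.amplitude_jitter,
                    )
                    path = generate_task_path(task, seed=int(s_path))
                    traj = add_tremor(
                        time_parameterize(task_path_scaled(path), task.base_speed,
                                          task.inter_stroke_pause),
                        trem,
                        seed=int(s_trem),
                    )
                    trace = sample_pen_trace(
                        traj,
                        jitter_sd=0.5e-3,
                        seed=int(s_pen),
                        participant_id=pid,
                        task_id=task.task_id,
                        condition=cond.condition,
                        repetition=rep,
                    )
                    task_onset = claps.clap_times[0] + claps.clap_duration_samples / ACCEL_FS + sync_offset
                    stream = generate_accel_stream(
                        duration=task_onset + traj.duration + 0.5,
                        tremor=trem,
                        claps=claps,
                        voluntary=VoluntarySpec(),
                        noise_sd=0.03,
                        seed=int(s_acc),
                        task_onset=task_onset,
                    )
                    stem = f"{pid}_{task.task_id}_{cond.condition}_r{rep}"
                    pen_file = f"traces/{stem}_pen.csv"
                    accel_file = f"traces/{stem}_accel.csv"
                    write_pen_trace(trace, out / pen_file)
                    write_accel_stream(stream, out / accel_file)
                    rows.append(
                        dict(participant=pid, task=task.task_id, condition=cond.condition,
                             repetition=rep, pen_file=pen_file, accel_file=accel_file)
                    )
                    truth.append(
                        dict(participant=pid, task=task.task_id, condition=cond.condition,
                             repetition=rep, tremor_frequency=trem.frequency,
                             amplitude_px=amp_px, amplitude_g=amp_g,
                             intercept=intercepts[p], condition_effect=cond.effect,
                             task_onset=task_onset, base_speed=task.base_speed)
                    )
                    idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth).to_csv(out / "ground_truth.csv", index=False, float_format="%.10g")
    return manifest


def task_path_scaled(path: list[np.ndarray]) -> list[np.ndarray]:
    """Hook for future per-participant spatial scaling; identity for now."""
    return path


def simulate_trial_outcomes(
    n_participants: int = 9,
    intercept_sd: float = 2.0,
    residual_sd: float = 1.0,
    condition_effects: dict[str, float] | None = None,
    baseline: float = 10.0,
    repetitions: int = 1,
    task: str = "spiral",
    outcome_name: str = "outcome",
    seed: int = 0,
) -> "pd.DataFrame":
    """Simulate a long-format trial table directly at the outcome level.

    y_ijk = baseline + effect(condition_j) + b_i + e_ijk with
    b_i ~ N(0, intercept_sd^2) and e ~ N(0, residual_sd^2).  Effects are
    additive shifts in outcome units; all-zero effects embed the null, so
    the generating distribution is identical across conditions.  This is the
    workhorse for calibration (type-I error, power, variance recovery) of the
    mixed-model stage.
    """
    import pandas as pd

    effects = dict.fromkeys(CONDITIONS, 0.0)
    if condition_effects:
        effects.update(condition_effects)
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, intercept_sd, n_participants)
    rows = []
    for i in range(n_participants):
        for cond in CONDITIONS:
            for rep in range(1, repetitions + 1):
                rows.append(
                    dict(
                        participant=f"P{i + 1:02d}",
                        task=task,
                        condition=cond,
                        repetition=rep,
                        outcome=outcome_name,
                        value=baseline + effects[cond] + b[i]
                        + rng.normal(0.0, residual_sd),
                    )
                )
    return pd.DataFrame(rows)
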