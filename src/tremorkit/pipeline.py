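"""End-to-end runner: simulate -> extract-tablet -> extract-accel -> analyze.

Each stage logs its parameters, writes its table with the config hash, and
is deterministic for a fixed seed, so a rerun reproduces every table
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import accel_features as af
from . import stats_compare as sc
from . import synthetic_data as sd
from . import tablet_kinematics as tk
from .config import PipelineConfig
from .core import CONDITIONS, TASKS
from .io import read_accel_stream, read_manifest, read_pen_trace, read_table, write_table

__all__ = ["simulate", "extract_tablet", "extract_accel", "analyze", "run_pipeline"]

log = logging.getLogger("tremorkit")


def _cohort_spec(cfg: PipelineConfig) -> sd.CohortSpec:
    s = cfg.simulate
    effects = {"none": s.effect_none, "low": s.effect_low, "high": s.effect_high}
    return sd.CohortSpec(
        n_participants=s.n_participants,
        tasks=tuple(
            sd.TaskSpec(t, base_speed=s.base_speed, inter_stroke_pause=s.inter_stroke_pause)
            for t in TASKS
        ),
        conditions=tuple(sd.ConditionSpec(c, effects[c]) for c in CONDITIONS),
        repetitions=s.repetitions,
        tremor=sd.TremorSpec(
            frequency=s.tremor_frequency,
            amplitude_px=s.tremor_amplitude_px,
            amplitude_g=s.tremor_amplitude_g,
        ),
        intercept_sd=s.intercept_sd,
        residual_sd=s.residual_sd,
        seed=cfg.seed,
    )


def simulate(cfg: PipelineConfig, out_dir) -> Path:
    """Generate the simulated cohort; returns the manifest path."""
    cfg.validate()
    out = Path(out_dir)
    log.info("simulate: n=%d seed=%d -> %s", cfg.simulate.n_participants, cfg.seed, out)
    t0 = time.time()
    sd.generate_cohort(_cohort_spec(cfg), out)
    (out / "provenance.json").write_text(
        json.dumps(
            {"seed": cfg.seed, "config_hash": cfg.hash(), "written_at": time.strftime("%Y-%m-%dT%H:%M:%S")},
            indent=2,
        )
    )
    cfg.save(out / "config.yaml")
    log.info("simulate: done in %.1fs", time.time() - t0)
    return out / "manifest.csv"


def extract_tablet(cfg: PipelineConfig, manifest_path, out_path) -> pd.DataFrame:
    """Compute tablet metrics for every repetition in the manifest."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    rows = []
    for _, r in manifest.iterrows():
        trace = read_pen_trace(root / r["pen_file"])
        m = tk.compute_tablet_metrics(
            trace,
            fs=cfg.tablet.fs,
            cutoff=cfg.tablet.cutoff,
            order=cfg.tablet.order,
            zero_phase=cfg.tablet.zero_phase,
        )
        rows.append(
            dict(participant=r["participant"], task=r["task"], condition=r["condition"],
                 repetition=r["repetition"], **m.as_dict())
        )
    df = pd.DataFrame(rows)
    write_table(df, out_path, config_hash=cfg.hash())
    log.info("extract-tablet: %d repetitions -> %s", len(df), out_path)
    return df


def extract_accel(cfg: PipelineConfig, manifest_path, out_path) -> pd.DataFrame:
    """Clap-synchronize, segment, and featurize every accel stream."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    a = cfg.accel
    rows = []
    for _, r in manifest.iterrows():
        stream = read_accel_stream(root / r["accel_file"], expected_fs=a.fs)
        claps = af.detect_claps(stream, power_threshold=a.clap_threshold, min_run=a.clap_min_run)
        if not claps:
            log.warning("no clap found in %s; skipping", r["accel_file"])
            continue
        seg = af.segment_by_clap(stream, claps[0], task_window=None, offset=a.sync_offset)
        feats = af.compute_signal_features(
            seg, cutoff=a.cutoff, order=a.order, literal_filtering=a.literal_filtering
        )
        rows.append(
            dict(participant=r["participant"], task=r["task"], condition=r["condition"],
                 repetition=r["repetition"], clap_time=claps[0].start_time, **feats)
        )
    df = pd.DataFrame(rows)
    write_table(df, out_path, config_hash=cfg.hash())
    log.info("extract-accel: %d segments -> %s", len(df), out_path)
    return df


def analyze(cfg: PipelineConfig, tablet_path, accel_path, out_dir) -> pd.DataFrame:
    """Fit the mixed models and write results.csv + report.txt + descriptives."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tablet = read_table(tablet_path, expect_hash=cfg.hash())
    accel = read_table(accel_path, expect_hash=cfg.hash()) if accel_path else None
    results, descr, report = sc.analyze_all(
        tablet, accel, method=cfg.stats.method,
        average_repetitions=cfg.stats.average_repetitions,
    )
    write_table(results, out / "results.csv", config_hash=cfg.hash())
    write_table(descr, out / "descriptives.csv", config_hash=cfg.hash())
    (out / "report.txt").write_text(report)
    log.info("analyze: %d model rows -> %s", len(results), out / "results.csv")
    return results


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict[str, Path]:
    """Run simulate -> extract-tablet -> extract-accel -> analyze.

    Returns the paths of the artifacts.  Idempotent for a fixed seed and
    config: every table is byte-identical across reruns.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        manifest = simulate(cfg, out)
        stage = "extract-tablet"
        extract_tablet(cfg, manifest, out / "metrics_tablet.csv")
        stage = "extract-accel"
        extract_accel(cfg, manifest, out / "features_accel.csv")
        stage = "analyze"
        analyze(cfg, out / "metrics_tablet.csv", out / "features_accel.csv", out / "results")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "manifest": manifest,
        "metrics_tablet": out / "metrics_tablet.csv",
        "features_accel": out / "features_accel.csv",
        "results": out / "results" / "results.csv",
        "report": out / "results" / "report.txt",
    }
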