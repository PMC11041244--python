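"""Pipeline configuration: every tunable the analysis exposes, with the
acquisition-matched defaults (142 Hz tablet, 128 Hz accel, 3.5 Hz / 5th-order
Butterworth, clap threshold 0.17 over 110 samples, 0.5 Hz bands 2-12 Hz).

Configs serialize to YAML and round-trip losslessly; a short hash of the
canonical serialization stamps every derived table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SimulateConfig", "TabletConfig", "AccelConfig", "StatsConfig"]


@dataclass
class SimulateConfig:
    n_participants: int = 9
    repetitions: int = 1
    tremor_frequency: float = 6.5
    tremor_amplitude_px: float = 4.0
    tremor_amplitude_g: float = 0.15
    intercept_sd: float = 1.0
    residual_sd: float = 0.5
    # tremor-amplitude multipliers per condition; all 1.0 embeds the null
    effect_none: float = 1.0
    effect_low: float = 1.0
    effect_high: float = 1.0
    base_speed: float = 150.0
    inter_stroke_pause: float = 0.5


@dataclass
class TabletConfig:
    fs: float = 142.0
    cutoff: float = 3.5
    order: int = 5
    zero_phase: bool = False


@dataclass
class AccelConfig:
    fs: float = 128.0
    cutoff: float = 3.5
    order: int = 5
    clap_threshold: float = 0.17
    clap_min_run: int = 110
    sync_offset: float = 1.0
    literal_filtering: bool = False
    # twenty-four half-Hz energy bands starting at band_lo
    band_lo: float = 2.0
    n_bands: int = 24
    band_width: float = 0.5


@dataclass
class StatsConfig:
    method: str = "f"  # "f" (containment-df Wald F) or "lrt"
    average_repetitions: bool = True
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    tablet: TabletConfig = field(default_factory=TabletConfig)
    accel: AccelConfig = field(default_factory=AccelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.simulate.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name, val in (("tablet.fs", self.tablet.fs), ("accel.fs", self.accel.fs),
                          ("tablet.cutoff", self.tablet.cutoff),
                          ("accel.cutoff", self.accel.cutoff),
                          ("accel.clap_threshold", self.accel.clap_threshold)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accel.clap_min_run < 1:
            raise ValueError("clap_min_run must be >= 1")
        if self.stats.method not in ("f", "lrt"):
            raise ValueError("stats.method must be 'f' or 'lrt'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            sub = d[f.name]
            if f.name == "seed":
                kw["seed"] = int(sub)
            else:
                kw[f.name] = f.default_factory().__class__(**sub)  # type: ignore[misc]
        return cls(**kw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        cfg = cls.from_dict(yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
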