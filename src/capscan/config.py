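"""Run configuration: namespaced keys, strict validation, paper-constant defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any

import yaml


@dataclass
class FilterConfig:
    low_hz: float = 0.25
    high_hz: float = 40.0


@dataclass
class ArtifactConfig:
    threshold_uv: float = 100.0
    rejection_window_s: float = 0.5


@dataclass
class BaselineConfig:
    window_s: float = 60.0


@dataclass
class DetectConfig:
    amplitude_factor: float = 1.5
    min_a_s: float = 2.0
    max_a_s: float = 60.0
    min_b_s: float = 2.0
    min_cycles: int = 2


@dataclass
class FeatureConfig:
    retain_variance: float = 0.96


@dataclass
class DatasetConfig:
    steps: int = 10


@dataclass
class TrainConfig:
    epochs: int = 50
    n_recurrent_layers: int = 2
    units_per_layer: int = 128
    dropout: float = 0.3
    dense_units: int = 64
    batch_size: int = 32
    learning_rate: float = 0.001


@dataclass
class PsoConfig:
    swarm_size: int = 30
    iterations: int = 50
    c1: float = 2.0
    c2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4


@dataclass
class EvalConfig:
    n_boot: int = 1000
    kappa_high: float = 0.85


@dataclass
class CapRateConfig:
    pathology_threshold_pct: float = 30.0


@dataclass
class SimulateConfig:
    fs: float = 128.0
    duration_s: float = 120.0
    baseline_amp_uv: float = 10.0
    noise_level: float = 0.0


@dataclass
class RunConfig:
    """All stage configs under namespaced keys plus the global seed.

    Defaults are the method's printed constants: 0.25-40 Hz band, 100 uV
    artifact threshold, 1.5x baseline / 2-60 s / >=2 s phase rules, 96%
    retained variance, 10 time steps, 50 epochs, swarm 30 with c = 2.0 and
    inertia 0.9 -> 0.4 over 50 iterations, 1000 bootstraps, kappa 0.85 and
    the 30% CAP-rate pathology threshold.
    """

    seed: int = 0
    log_level: str = "INFO"
    filter: FilterConfig = field(default_factory=FilterConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    cap_rate: CapRateConfig = field(default_factory=CapRateConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        """Build from a nested mapping; unknown keys raise with their name."""
        kwargs: dict[str, Any] = {}
        section_types = {f.name: f.type for f in fields(cls)}
        sections = {
            "filter": FilterConfig,
            "artifact": ArtifactConfig,
            "baseline": BaselineConfig,
            "detect": DetectConfig,
            "features": FeatureConfig,
            "dataset": DatasetConfig,
            "train": TrainConfig,
            "pso": PsoConfig,
            "evaluation": EvalConfig,
            "cap_rate": CapRateConfig,
            "simulate": SimulateConfig,
        }
        for key, value in data.items():
            if key in ("seed", "log_level"):
                kwargs[key] = value
            elif key in sections:
                sub = sections[key]
                valid = {f.name for f in fields(sub)}
                unknown = set(value) - valid
                if unknown:
                    raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {key!r}")
                kwargs[key] = sub(**value)
            else:
                raise ValueError(f"unknown config section {key!r}")
        _ = section_types
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Stage-specific seed derived from the global seed by name hashing."""
        h = 0
        for ch in stage:
            h = (h * 31 + ord(ch)) % 100_000
        return (self.seed * 100_000 + h) % (2**31 - 1)
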