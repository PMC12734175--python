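"""Experiment configuration: one YAML file drives every CLI command.

Layout::

    model:      BranchConfig fields (plus optional ``preset: tiny|full``)
    training:   TrainConfig fields
    data:       exactly one of ``path`` (class-per-directory image tree)
                or ``synthetic`` (SyntheticDatasetSpec fields)
    strategy:   fusion strategy name
    output_dir: where artifacts are written
    log_level:  python logging level name

Validation reports the dotted path of the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .branches import BranchConfig
from .data.synthetic import SyntheticDatasetSpec
from .fusion import FUSION_STRATEGIES
from .training import TrainConfig
from .utils import config_hash

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration problem, reported with the offending field path."""


def _build(cls, payload: dict, where: str, presets: dict | None = None):
    if not isinstance(payload, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(payload).__name__}")
    payload = dict(payload)
    preset = payload.pop("preset", None)
    if presets is not None and preset is not None:
        if preset not in presets:
            raise ConfigError(f"{where}.preset: unknown preset {preset!r}")
        base = dataclasses.asdict(presets[preset]())
    else:
        base = {}
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in valid:
            raise ConfigError(f"{where}.{key}: unknown field (valid: "
                              f"{', '.join(sorted(valid))})")
    base.update(payload)
    if "classes" in base and isinstance(base["classes"], list):
        base["classes"] = tuple(base["classes"])
    try:
        return cls(**base)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class ExperimentConfig:
    model: BranchConfig = field(default_factory=BranchConfig.tiny)
    training: TrainConfig = field(default_factory=TrainConfig)
    data_path: Path | None = None
    synthetic: SyntheticDatasetSpec | None = None
    strategy: str = "gsaf"
    output_dir: Path = Path("runs")
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.data_path is None) == (self.synthetic is None):
            raise ConfigError(
                "data: exactly one of 'path' or 'synthetic' must be given")
        if self.strategy not in FUSION_STRATEGIES:
            raise ConfigError(f"strategy: unknown strategy {self.strategy!r}; "
                              f"choose from {FUSION_STRATEGIES}")

    @property
    def hash(self) -> str:
        payload = {
            "model": dataclasses.asdict(self.model),
            "training": dataclasses.asdict(self.training),
            "data": str(self.data_path) if self.data_path
                    else dataclasses.asdict(self.synthetic),
            "strategy": self.strategy,
        }
        return config_hash(payload)

    def with_strategy(self, strategy: str) -> "ExperimentConfig":
        return dataclasses.replace(self, strategy=strategy)

    def with_training(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, training=self.training.with_(**kw))


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"model", "training", "data", "strategy", "output_dir", "log_level"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"{key}: unknown top-level section "
                              f"(valid: {', '.join(sorted(known))})")

    model = _build(BranchConfig, raw.get("model", {"preset": "tiny"}), "model",
                   presets={"tiny": BranchConfig.tiny, "full": BranchConfig.full})
    training = _build(TrainConfig, raw.get("training", {}), "training")

    data = raw.get("data", {})
    if not isinstance(data, dict):
        raise ConfigError("data: expected a mapping")
    data_path = data.get("path")
    synthetic = None
    if "synthetic" in data:
        synthetic = _build(SyntheticDatasetSpec, data["synthetic"],
                           "data.synthetic")
    return ExperimentConfig(
        model=model, training=training,
        data_path=Path(data_path) if data_path else None,
        synthetic=synthetic,
        strategy=raw.get("strategy", "gsaf"),
        output_dir=Path(raw.get("output_dir", "runs")),
        log_level=str(raw.get("log_level", "INFO")),
    )
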