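"""Run configuration: every tunable of the end-to-end study in one object.

The printed clinical constants live here as defaults: the 6-h feature
window, the 22-mmHg treatment threshold, the > 5 min (IH) and > 1 h (SIH)
durations, and the 18-h minimum recording length.  Configurations load from
YAML with strict key checking (unknown keys are rejected) so a manifest
plus a seed reproduces a study bundle exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .complexity import ComplexityParams
from .rf_pipeline import RFConfig, SplitSpec
from .simcohort import GroupEffect, SimConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    complexity: ComplexityParams = field(default_factory=ComplexityParams)
    rf: RFConfig = field(default_factory=RFConfig)

    epoch_s: float = 12.0
    smooth_span: int = 4
    feature_window_h: float = 6.0
    ih_threshold_mmHg: float = 22.0
    ih_min_duration_min: float = 5.0
    sih_min_duration_min: float = 60.0
    min_record_h: float = 18.0
    artifact_max_invalid_frac: float = 0.30
    early_ih_epoch_frac: float = 0.80
    prx_window_epochs: int = 30
    rap_window_epochs: int = 30
    train_fraction: float = 0.7
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if self.smooth_span < 1:
            raise ValueError("smooth_span must be >= 1")
        if not 0 < self.feature_window_h < self.min_record_h:
            raise ValueError("feature_window_h must lie inside the recording")
        if self.ih_threshold_mmHg <= 0:
            raise ValueError("ih_threshold_mmHg must be positive")
        if self.sih_min_duration_min <= self.ih_min_duration_min:
            raise ValueError("SIH duration must exceed IH duration")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if min(self.prx_window_epochs, self.rap_window_epochs) < 3:
            raise ValueError("correlation windows must be >= 3 epochs")

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, sim=replace(self.sim, seed=seed))


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path or cls.__name__}")
    return cls(**{f.name: data[f.name] for f in fields(cls) if f.name in data})


def _coerce_sim(data: dict) -> SimConfig:
    data = dict(data)
    # any field whose default is a GroupEffect accepts a dict or a 2/3-list
    group_fields = {
        f.name for f in fields(SimConfig) if isinstance(f.default, GroupEffect)
    }
    for key, v in data.items():
        if key in group_fields and isinstance(v, (list, tuple, dict)):
            data[key] = GroupEffect(**v) if isinstance(v, dict) else GroupEffect(*v)
    for key in ("ih_onset_hours_range", "ih_duration_min_range", "sih_duration_min_range"):
        if key in data:
            data[key] = tuple(data[key])
    return _build(SimConfig, data, "sim")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys, and validate."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    if "sim" in data:
        kwargs["sim"] = _coerce_sim(data.pop("sim"))
    if "complexity" in data:
        kwargs["complexity"] = _build(ComplexityParams, data.pop("complexity"), "complexity")
    if "rf" in data:
        rf = dict(data.pop("rf"))
        for key in ("mtry_grid", "min_node_grid"):
            if rf.get(key) is not None:
                rf[key] = tuple(rf[key])
        kwargs["rf"] = _build(RFConfig, rf, "rf")
    kwargs.update(data)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a RunConfig to YAML (returns the text; writes if path given)."""

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    text = yaml.safe_dump(enc(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
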