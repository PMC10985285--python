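"""Structured run configuration with strict key validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .encoding import HIT_VALUE, MISS_VALUE
from .nn.net import ModelConfig


@dataclass
class RunConfig:
    """All knobs of a run; unknown keys are rejected on load."""

    spec_name: str = "netmhcpan34"
    contact_cutoff: float = 4.0
    min_support: int = 1
    hit_value: float = HIT_VALUE
    miss_value: float = MISS_VALUE
    positive_anchor_nm: float = 100.0
    negative_anchor_nm: float = 10000.0
    decoy_threshold_nm: float = 1000.0
    classification_threshold: float = 0.5
    paired_ttest: bool = False
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["model"]["stage_depths"] = list(self.model.stage_depths)
        d["model"]["stage_widths"] = list(self.model.stage_widths)
        d["model"]["dw_kernel"] = list(self.model.dw_kernel)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; empty file means all defaults.

    Validation errors name the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    top_fields = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    model_raw = raw.pop("model", {}) or {}
    model_fields = {f.name for f in fields(ModelConfig)}
    unknown = set(model_raw) - model_fields
    if unknown:
        raise ValueError(f"unknown config key(s) under model: {sorted(unknown)}")
    for tup in ("stage_depths", "stage_widths", "dw_kernel"):
        if tup in model_raw:
            model_raw[tup] = tuple(model_raw[tup])
    try:
        model = ModelConfig(**model_raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid model config: {exc}") from exc
    cfg = RunConfig(model=model)
    for key, value in raw.items():
        expected = type(getattr(cfg, key))
        if expected in (int, float) and isinstance(value, (int, float)) and not isinstance(value, bool):
            value = expected(value)
        if not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected.__name__}, got {type(value).__name__}"
            )
        setattr(cfg, key, value)
    return cfg
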