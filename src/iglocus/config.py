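"""Run configuration: one YAML document covering every tunable threshold.

Each section maps onto a module-level dataclass so a config file fully
reproduces a run; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .annotate import AnnotationConfig
from .pipeline import AlignParams
from .rss import RssConfig


@dataclass
class RunConfig:
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    alignment: AlignParams = field(default_factory=AlignParams)
    family_threshold: float = 0.75
    ultralong_threshold: int = 50
    clonal_proportion_q: float = 0.31
    overlap_identity: str = "cdr3_aa"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    ann = data.pop("annotation", {})
    rss = ann.pop("rss", {}) if isinstance(ann, dict) else {}
    annotation = _build(AnnotationConfig, {**ann, "rss": _build(RssConfig, rss)})
    alignment = _build(AlignParams, data.pop("alignment", {}))
    cfg = _build(RunConfig, data)
    return dataclasses.replace(cfg, annotation=annotation, alignment=alignment)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
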