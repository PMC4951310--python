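"""Run configuration: YAML-backed parameter bundles for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .stains import StainConfig
from .stroma import StromaConfig
from .vessels import VesselAnalysisConfig
from .stats import CoxConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs besides the input manifest."""

    stains: StainConfig = field(default_factory=StainConfig)
    vessels: VesselAnalysisConfig = field(default_factory=VesselAnalysisConfig)
    stroma: StromaConfig = field(default_factory=StromaConfig)
    cox: CoxConfig = field(default_factory=CoxConfig)
    site_policy: str = "primary_else_metastasis"
    core_combiner: str = "mean"
    stroma_fraction_rule: str = "mean_split"
    perivascular_intensity_rule: str = "lowest_quartile_vs_rest"
    prognostic_metrics: tuple = ("pdgfrb_stroma_fraction", "pdgfrb_perivascular_intensity")
    seed: int = 0
    qc_overlays: bool = False


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; missing sections fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sub = {
        "stains": _build(StainConfig, raw.pop("stains", {})),
        "vessels": _build(VesselAnalysisConfig, raw.pop("vessels", {})),
        "stroma": _build(StromaConfig, raw.pop("stroma", {})),
        "cox": _build(CoxConfig, raw.pop("cox", {})),
    }
    cfg = _build(RunConfig, raw)
    for k, v in sub.items():
        setattr(cfg, k, v)
    return cfg
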