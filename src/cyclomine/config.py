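"""Pipeline configuration: one nested structure, TOML-serializable.

Every knob defaults to the value used throughout the package (mining
thresholds, loop windows, anchoring penalties, classification thresholds,
match parameters, FPKM cutoff, seed).  Unknown keys in a config file are an
error, never silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .classify import ClassifyParams
from .expression import FPKM_CUTOFF
from .mining import MiningParams
from .msmatch import MatchParams

__all__ = ["SyntheticConfig", "PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_species: int = 2
    n_decoys: int = 50
    utr_len: tuple[int, int] = (30, 120)
    fpkm_mu: float = 5.0
    fpkm_sigma: float = 1.2
    jitter_sd: float = 0.0
    n_isotope_peaks: int = 5
    n_noise_peaks: int = 0
    make_alkylated: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    mining: MiningParams = field(default_factory=MiningParams)
    anchoring_gap_open: float = 7.0
    anchoring_gap_extend: float = 1.0
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    match: MatchParams = field(default_factory=MatchParams)
    fpkm_cutoff: float = FPKM_CUTOFF
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key {path}{key!r}")
        f = names[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _build(f.type, value, f"{path}{key}.")
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "mining": MiningParams,
    "classify": ClassifyParams,
    "match": MatchParams,
    "synthetic": SyntheticConfig,
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML config; missing keys keep defaults, unknown keys error."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    top = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top:
            raise ValueError(f"unknown config key {key!r}")
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value, f"{key}.")
        else:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
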