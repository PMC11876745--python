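"""Declarative study configuration.

One nested mapping drives every pipeline stage; all tunable thresholds
from every module surface here with their defaults.  Configs round-trip
through YAML, and `config_hash` is stable under re-serialization (the hash
is taken over a canonical key-sorted dump).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .sleepcode import SleepThresholds
from .synth import AS_RESP_DEFAULT, QS_RESP_DEFAULT, BoutParams, RespGenParams

__all__ = ["StudyConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class StudyConfig:
    # study layout
    n_infants: int = 11
    session_s: float = 3600.0
    runs_min: int = 3
    runs_max: int = 7
    n_nodes: int = 89
    n_volumes: int = 90
    tr: float = 2.0
    seed: int = 42
    # synthetic generator
    bout: BoutParams = field(default_factory=BoutParams)
    resp_as: RespGenParams = field(default_factory=lambda: AS_RESP_DEFAULT)
    resp_qs: RespGenParams = field(default_factory=lambda: QS_RESP_DEFAULT)
    motion_outlier_prob: float = 0.08
    effect_edges: tuple[int, ...] = ()
    effect_delta_z: float = 0.0
    # respiration conditioning
    bandpass_low_hz: float = 0.05
    bandpass_high_hz: float = 5.0
    epoch_s: float = 30.0
    thresholds: SleepThresholds = field(default_factory=SleepThresholds)
    # connectome
    fd_threshold_mm: float = 0.15
    head_radius_mm: float = 50.0
    smooth_cutoff_hz: float = 0.12
    # stats
    adjust: bool = False
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(d: dict) -> StudyConfig:
    d = dict(d)
    if "bout" in d and isinstance(d["bout"], dict):
        d["bout"] = BoutParams(**d["bout"])
    for key in ("resp_as", "resp_qs"):
        if key in d and isinstance(d[key], dict):
            d[key] = RespGenParams(**d[key])
    if "thresholds" in d and isinstance(d["thresholds"], dict):
        th = dict(d["thresholds"])
        for band in ("qs_freq_band", "as_freq_band", "eval_band"):
            if band in th:
                th[band] = tuple(th[band])
        d["thresholds"] = SleepThresholds(**th)
    if "effect_edges" in d:
        d["effect_edges"] = tuple(d["effect_edges"])
    return StudyConfig(**d)


def load_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _coerce(data)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg.to_dict()), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(cfg: StudyConfig) -> str:
    canonical = yaml.safe_dump(_plain(cfg.to_dict()), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
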