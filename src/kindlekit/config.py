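"""Run configuration: one YAML document driving the whole pipeline.

Defaults reproduce the published protocol and analysis constants: the
20+1-stimulus rapid-kindling protocol at 2000 Hz over channels PC/HIP/AMYG,
the 2x / 3 s afterdischarge rule, the classical band edges up to 100 Hz,
and the dyad thresholds chi2 >= 3.84 / log10(chi2) >= 0.25.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .eeg_events import DetectorParams
from .neuroethology import CHI2_CRITICAL, LOG_CHI2_CRITICAL
from .spectral import DEFAULT_BANDS, BandDefinition
from .synthdata import GroupEffects, NoiseSpec, ProtocolConfig

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


@dataclass
class RunConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    effects: GroupEffects = field(default_factory=GroupEffects)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    dyad_chi2_min: float = CHI2_CRITICAL
    dyad_log_chi2_min: float = LOG_CHI2_CRITICAL
    n_per_group: int = 8
    seed: int = 0
    eeg_stimuli: tuple[int, ...] = (1, 21)
    behavior_stimuli: tuple[int, ...] = (21,)
    spectral_window: str = "none"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.spectral_window not in ("none", "hann"):
            raise ValueError("spectral_window must be 'none' or 'hann'")
        if self.dyad_chi2_min <= 0:
            raise ValueError("dyad chi-square threshold must be positive")
        bad = [s for s in (*self.eeg_stimuli, *self.behavior_stimuli)
               if not 1 <= s <= self.protocol.n_stimuli]
        if bad:
            raise ValueError(f"stimulus indices {bad} outside the protocol (1..{self.protocol.n_stimuli})")


def _as_payload(config: RunConfig) -> dict:
    payload = asdict(config)
    payload["bands"] = [
        {"name": b.name, "low_hz": b.low_hz, "high_hz": b.high_hz} for b in config.bands
    ]
    payload["protocol"]["channels"] = list(config.protocol.channels)
    payload["eeg_stimuli"] = list(config.eeg_stimuli)
    payload["behavior_stimuli"] = list(config.behavior_stimuli)
    return payload


def dump_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_as_payload(config), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "protocol" in kwargs:
        proto = dict(kwargs["protocol"])
        proto["channels"] = tuple(proto.get("channels", ("PC", "HIP", "AMYG")))
        kwargs["protocol"] = ProtocolConfig(**proto)
    if "detector" in kwargs:
        kwargs["detector"] = DetectorParams(**kwargs["detector"])
    if "effects" in kwargs:
        kwargs["effects"] = GroupEffects(**kwargs["effects"])
    if "noise" in kwargs:
        kwargs["noise"] = NoiseSpec(**kwargs["noise"])
    if "bands" in kwargs:
        kwargs["bands"] = tuple(BandDefinition(**b) for b in kwargs["bands"])
    for key in ("eeg_stimuli", "behavior_stimuli"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration (stamped on outputs)."""
    text = yaml.safe_dump(_as_payload(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
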