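"""Nested pipeline configuration with strict-key YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .artifact_removal import SAMPEN_THRESHOLD, SampEnParams
from .classifier import NetworkParams
from .features import WaveletConfig
from .namemd import NAMEMDConfig
from .signal_model import SyntheticConfig, TrialTiming


@dataclass
class PreprocessingConfig:
    target_fs_hz: float = 250.0
    low_hz: float = 3.0
    high_hz: float = 30.0


@dataclass
class OnlineConfig:
    first_s: float = 2.5
    step_s: float = 0.5
    window_s: float = 2.5
    majority_vote: bool = False
    n_sessions: int = 10


@dataclass
class StatsConfig:
    alpha: float = 0.05
    sampen_threshold: float = SAMPEN_THRESHOLD


@dataclass
class PipelineConfig:
    """All stage configurations in one round-trippable object."""

    generator: SyntheticConfig = field(default_factory=SyntheticConfig)
    timing: TrialTiming = field(default_factory=TrialTiming)
    preprocessing: PreprocessingConfig = field(
        default_factory=PreprocessingConfig)
    namemd: NAMEMDConfig = field(default_factory=NAMEMDConfig)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    online: OnlineConfig = field(default_factory=OnlineConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    n_sessions: int = 10

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = asdict(v) if hasattr(v, "__dataclass_fields__") else v
        # tuples serialize as lists; normalise for round-trip equality
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, val in d.items():
            if key not in known:
                raise KeyError(f"unknown configuration key: {key!r}")
            f = known[key]
            if isinstance(val, dict):
                section_cls = f.default_factory  # type: ignore[union-attr]
                sec_fields = {sf.name for sf in fields(section_cls)}
                bad = set(val) - sec_fields
                if bad:
                    raise KeyError(
                        f"unknown configuration key: {key}.{sorted(bad)[0]}")
                val = section_cls(**{k: _tuplify(v) for k, v in val.items()})
            kwargs[key] = val
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(obj):
    return tuple(obj) if isinstance(obj, list) else obj
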