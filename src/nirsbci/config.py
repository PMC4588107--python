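"""Run configuration: one serializable object holding every knob of the
pipeline, so each output is re-derivable from config + seed alone."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import FilterSpec
from .simulate import EffectSpec, NoiseSpec, ParticipantSpec


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """End-to-end pipeline settings (all overridable from YAML/JSON)."""

    seed: int = 0
    n_sessions: int = 5
    n_blocks: int = 3
    reps_per_block: int = 4
    fs: float = 31.25
    n_range: tuple[int, ...] = (2, 3, 4, 5)
    cv_folds: int = 10
    cv_iterations: int = 10
    chance_alpha: float = 0.05
    correlation_alpha: float = 0.1
    fcbf_delta: float = 0.0
    fcbf_bins: int = 10
    effect_amplitude_uM: float = 0.6
    iq_coupling: float = 0.0
    n_participants: int = 10
    output_dir: str = "results"
    zero_phase_filter: bool = False

    def __post_init__(self):
        if not 0 < self.chance_alpha < 1 or not 0 < self.correlation_alpha < 1:
            raise ConfigError("alpha values must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("need at least 2 CV folds")
        if any(not 2 <= n <= 6 for n in self.n_range):
            raise ConfigError("class counts must lie in 2..6")

    # -- component specs -------------------------------------------------
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(fs=self.fs)

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(amplitude_uM=self.effect_amplitude_uM)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec()

    def participant_spec(self) -> ParticipantSpec:
        return ParticipantSpec(n_participants=self.n_participants,
                               iq_coupling=self.iq_coupling)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_range"] = list(self.n_range)
        return d

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        obj = dict(obj)
        if "n_range" in obj:
            obj["n_range"] = tuple(obj["n_range"])
        return cls(**obj)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        obj = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(obj or {})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
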