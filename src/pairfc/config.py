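"""Run configuration: one YAML-serializable object covering every stage.

All randomness in a run flows from the named seeds recorded here; a saved
resolved configuration therefore suffices to reproduce the run exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynfc import SlidingWindowConfig
from .training import LossConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class AttentionConfig:
    d_k: int | None = None  # None: use K
    identity_gain: float = 3.0
    seed: int = 0


@dataclass
class ProtocolConfig:
    n_shot: int = 5
    n_query: int = 5
    n_episodes: int = 100
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    episode_seed: int = 0
    aggregation: str = "mean"
    decision_rule: str = "class_mean"


@dataclass
class SimulateConfig:
    n_rois: int = 20
    n_timepoints: int = 137
    n_subjects_per_group: int = 40
    scans_per_subject: int = 1
    n_altered_pairs: int = 5
    effect_size: float = 0.6
    effect_sign: int = -1
    base_coupling: float = 0.35
    noise_sd: float = 0.1
    seed: int = 0


@dataclass
class RunConfig:
    window_length: int = 30
    step: int = 2
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    manifest: str | None = None  # None: simulate a cohort
    output_dir: str = "pairfc_run"

    def window(self) -> SlidingWindowConfig:
        return SlidingWindowConfig(self.window_length, self.step)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"]["split_fractions"] = list(self.protocol.split_fractions)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        def build(klass, value):
            if isinstance(value, klass):
                return value
            names = {f.name for f in fields(klass)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**value)

        for key, klass in (
            ("attention", AttentionConfig),
            ("loss", LossConfig),
            ("training", TrainConfig),
            ("protocol", ProtocolConfig),
            ("simulate", SimulateConfig),
        ):
            if key in raw:
                raw[key] = build(klass, raw[key])
        cfg = cls(**raw)
        cfg.protocol.split_fractions = tuple(cfg.protocol.split_fractions)
        return cfg

    def reseed(self, seed: int) -> "RunConfig":
        """Derive every stage seed deterministically from one master seed."""
        import numpy as np

        rng = np.random.default_rng(seed)
        draws = rng.integers(2**31, size=5)
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.simulate.seed = int(draws[0])
        cfg.attention.seed = int(draws[1])
        cfg.training = TrainConfig(
            **{**asdict(cfg.training), "seed": int(draws[2])}
        )
        cfg.protocol.split_seed = int(draws[3])
        cfg.protocol.episode_seed = int(draws[4])
        return cfg


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
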