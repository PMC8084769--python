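"""Run configuration: YAML/JSON-serialisable settings for the pipeline.

A :class:`RunConfig` names the experiment design, the simulated observer,
the optimiser settings and the seed; ``load -> dump -> load`` is an
identity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelParams
from .observer import ExperimentConfig, ObserverParams

__all__ = ["RunConfig", "load_config", "dump_config"]

_EXPERIMENTS = ("exp1", "exp2")


@dataclass(frozen=True)
class RunConfig:
    experiment: str = "exp2"
    seed: int = 0
    output_dir: str = "results"
    n_participants: int | None = None
    repetitions: int = 10
    observer: ObserverParams = field(default_factory=ObserverParams)
    fitting: dict = field(default_factory=lambda: {"n_starts": 32})

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"experiment must be one of {_EXPERIMENTS}")

    def experiment_config(self) -> ExperimentConfig:
        kwargs = {"seed": self.seed, "repetitions": self.repetitions}
        if self.n_participants is not None:
            kwargs["n_participants"] = self.n_participants
        if self.experiment == "exp1":
            return ExperimentConfig.exp1(**kwargs)
        return ExperimentConfig.exp2(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        obs = d.get("observer", {})
        if isinstance(obs, dict):
            obs = dict(obs)
            model = obs.get("model", {})
            if isinstance(model, dict):
                obs["model"] = ModelParams(**model)
            d["observer"] = ObserverParams(**obs)
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return RunConfig.from_dict(data)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid config field: {exc}") from exc


def dump_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
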