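"""Run configuration snapshots.

A :class:`RunConfig` merges every dataclass that shapes a run — phantom
spec, network and training configuration, normalization constants, seeds
and paths — and serializes to YAML so that a finished run directory fully
describes how to reproduce it.  Reloading a snapshot reconstructs the
configuration bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hu_windows import NormalizationSpec, TissueWindows
from .phantom import PhantomSpec
from .training import TrainConfig
from .unet import DESK_PROFILE, NetworkConfig


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _tuplify(cls, data: dict):
    """Rebuild a dataclass, restoring tuple fields YAML turned into lists."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        v = data[f.name]
        kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    network: NetworkConfig = DESK_PROFILE
    training: TrainConfig = field(default_factory=TrainConfig)
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    windows: TissueWindows = field(default_factory=TissueWindows)
    seed: int = 0
    cohort_path: str = ""
    run_dir: str = ""

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            phantom=_tuplify(PhantomSpec, data["phantom"]),
            network=_tuplify(NetworkConfig, data["network"]),
            training=_tuplify(TrainConfig, data["training"]),
            normalization=_tuplify(NormalizationSpec, data["normalization"]),
            windows=_tuplify(TissueWindows, data["windows"]),
            seed=data["seed"],
            cohort_path=data["cohort_path"],
            run_dir=data["run_dir"],
        )
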