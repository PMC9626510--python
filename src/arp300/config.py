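"""Run configuration: one declarative object drives the whole pipeline.

Loaded from TOML or YAML; unknown keys are rejected with an explicit error.
Every stage derives its own seed deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "load_config", "stage_seed"]

_STAGES = ("schedule", "session", "train", "crossval")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    # protocol / simulation
    environment: str = "ar"
    runs: int = 10
    blocks_per_run: int = 9
    trials_per_block: int = 5
    n_stimuli: int = 9
    soa_ms: int = 175
    flash_ms: int = 100
    prep_ms: int = 2000
    lock_ms: int = 1500
    sim: dict = field(default_factory=dict)  # SimParams overrides
    # preprocessing
    lo_hz: float = 0.1
    hi_hz: float = 12.0
    window_ms: float = 600.0
    downsample: int = 3
    drop_channels: list = field(default_factory=lambda: ["A1", "A2"])
    # model + training
    model: str = "sepcnn"
    train: dict = field(default_factory=dict)  # TrainHyper / baseline overrides
    # evaluation
    folds: int = 5
    averages: int = 1
    itr_n_targets: int = 9
    itr_selection_time_s: float = 2.0
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in ("sepcnn", "cnn", "lda", "blda", "swlda", "svm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.environment not in ("ar", "cs"):
            raise ValueError(f"unknown environment {self.environment!r}")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read a TOML (or YAML) config file and apply CLI overrides."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return RunConfig(**raw)
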