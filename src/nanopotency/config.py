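"""Declarative pipeline configuration and per-run reporting."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Key-value configuration shared by the CLI subcommands.

    Unknown keys in a config file are rejected so typos fail loudly.
    Stochastic stages refuse to run without a seed.
    """

    # inputs / outputs
    plate: str | None = None
    physchem: str | None = None
    markers: str | None = None
    treated: str | None = None
    control: str | None = None
    gmt: str | None = None
    out_dir: str = "."

    # design parameters (simulate)
    particles: list = field(default_factory=lambda: [f"NP-{i:02d}" for i in range(1, 9)])
    cell_lines: list = field(default_factory=lambda: ["A549", "J774A.1"])
    doses: list = field(
        default_factory=lambda: [0.0, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0]
    )
    n_experiments: int = 3
    n_technical: int = 2
    mechanistic_dose: float = 30.0
    true_beta: float = 0.03
    noise_cv: float = 0.1
    planted_property: str = "bet_sa"
    planted_r: float = 0.9
    marker_r: float = -0.8
    universe_size: int = 400
    n_sets: int = 10
    set_size: int = 15
    n_reps: int = 3
    perturbed_set: str | None = "SET000"
    perturbed_log2_effect: float = 2.0

    # analysis parameters
    subtract_cell_free: bool = False
    on_means: bool = False
    precision: int = 3
    rank_transform: bool = True
    anova_factors: list = field(default_factory=lambda: ["particle", "dose"])
    correlation_method: str = "pearson"
    min_obs: int = 2
    n_perm: int = 1000
    weight: float = 1.0
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    z_cutoff: float = 2.0
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"

    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def updated(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("this stage is stochastic: a seed is required")
        return int(self.seed)


@dataclass
class StageRecord:
    name: str
    n_input: int
    n_retained: int
    n_dropped: int
    drop_reasons: dict = field(default_factory=dict)
    seconds: float = 0.0

    def __post_init__(self):
        if self.n_input != self.n_retained + self.n_dropped:
            raise ValueError(
                f"stage {self.name!r}: input ({self.n_input}) != retained "
                f"({self.n_retained}) + dropped ({self.n_dropped})"
            )


@dataclass
class RunReport:
    """Reconciled per-stage accounting written next to each run's outputs."""

    command: str
    version: str
    config: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def add_stage(
        self,
        name: str,
        n_input: int,
        n_retained: int,
        drop_reasons: dict | None = None,
        seconds: float = 0.0,
    ) -> None:
        self.stages.append(
            StageRecord(
                name=name,
                n_input=n_input,
                n_retained=n_retained,
                n_dropped=n_input - n_retained,
                drop_reasons=drop_reasons or {},
                seconds=seconds,
            )
        )

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "version": self.version,
            "config": self.config,
            "stages": [asdict(s) for s in self.stages],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


class StageTimer:
    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.seconds = time.perf_counter() - self.start
        return False
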