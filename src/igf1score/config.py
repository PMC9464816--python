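"""Pipeline configuration: strict parsing, lossless YAML/JSON round trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the end-to-end pipeline run.

    When ``counts_ref``/``counts_cohort`` are unset the simulator
    provides the data (using ``simulation`` and ``seed``); otherwise the
    referenced files are read instead.
    """

    outdir: str = "igf1score_run"
    seed: int = 0
    log_level: str = "INFO"
    # stage parameters
    min_count: int = 5
    min_fraction: float = 1.0 / 3.0
    pseudocount: float = 1.0
    alpha: float = 0.05
    min_overlap: float = 0.5
    stratify_on: str = "marker_expression"
    pattern_column: str = "autoantibody_pattern"
    # inputs (optional; simulator used when absent)
    counts_ref: str | None = None
    groups_ref: str | None = None
    counts_cohort: str | None = None
    metadata_cohort: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            d["simulation"] = SimulationConfig.from_dict(sim)
        return cls(**d)


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
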