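"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .basis import DEFAULT_LAMBDA
from .preprocess import QCThresholds, WINDOW
from .simulate import SimulationParams


@dataclass
class RunConfig:
    """One structured config for simulate/preprocess/fpca/regress/report.

    Every threshold and smoothing default is the published value; the full
    config is serialized into each output directory so runs are reproducible
    and overrides are visible.
    """

    signals: str = "signals.csv"
    subject_table: str = "subjects.csv"
    output_dir: str = "out"
    sampling_rate: float = 50.0
    window: tuple[float, float] = WINDOW
    qc: QCThresholds = field(default_factory=QCThresholds)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    order: int = 4
    interior_knots: list[float] | None = None  # None -> default scheme
    lam: float = DEFAULT_LAMBDA
    n_retained: int | None = None  # None -> scree elbow
    elbow_method: str = "max_distance"
    bin_width: float = 10.0
    correlation: str = "pearson"
    outcome: str = "transition_time"
    covariates: list[str] = field(default_factory=list)
    standardized_scores: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = QCThresholds(**data["qc"])
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationParams(**data["simulation"])
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
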