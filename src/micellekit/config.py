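"""Run configuration: one YAML mapping driving the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .builder import BoxSpec, CHAIN_GEOMETRY
from .engine import EngineParams
from .errors import InvalidInputError


@dataclass
class AnalysisParams:
    """Aggregate-analysis knobs: contact cutoff (nm), free-size cutoff,
    late-run window fraction and snapshot count."""

    cutoff_nm: float = 0.6
    size_cutoff: int = 5
    window_fraction: float = 0.1
    n_snapshots: int = 20


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    chain_id: str = "C10"
    concentrations_mM: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    fraction_deprotonated: float = 1.0
    ionic_strength_mM: float = 140.0
    box_nm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    temperature_C: float = 37.0
    engine: EngineParams = field(default_factory=EngineParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    output_dir: str = "pipeline_out"

    def __post_init__(self):
        if self.chain_id not in CHAIN_GEOMETRY:
            raise InvalidInputError(f"unknown chain id {self.chain_id!r}")
        if not 0.0 <= self.fraction_deprotonated <= 1.0:
            raise InvalidInputError("fraction_deprotonated must lie in [0, 1]")
        if any(c < 0 for c in self.concentrations_mM):
            raise InvalidInputError("concentrations must be non-negative")

    @property
    def box(self) -> BoxSpec:
        return BoxSpec(*self.box_nm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["concentrations_mM"] = list(self.concentrations_mM)
        d["box_nm"] = list(self.box_nm)
        # epsilon table keys become "A-B" strings for YAML
        eps = d["engine"].pop("lj_epsilon")
        d["engine"]["lj_epsilon"] = {f"{a}-{b}": v for (a, b), v in eps.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        engine_d = dict(d.pop("engine", {}))
        if "lj_epsilon" in engine_d:
            engine_d["lj_epsilon"] = {
                tuple(k.split("-")): v for k, v in engine_d["lj_epsilon"].items()
            }
        if "equilibration" in engine_d and engine_d["equilibration"] is not None:
            engine_d["equilibration"] = [tuple(x) for x in engine_d["equilibration"]]
        analysis_d = dict(d.pop("analysis", {}))
        d["concentrations_mM"] = tuple(d.get("concentrations_mM", (30.0, 60.0, 90.0, 120.0)))
        d["box_nm"] = tuple(d.get("box_nm", (15.0, 15.0, 15.0)))
        return cls(engine=EngineParams(**engine_d), analysis=AnalysisParams(**analysis_d), **d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidInputError("config must be a YAML mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the canonicalised config."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
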