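"""Structured configuration for the simulation experiments.

All tunable model constants live in a YAML file (see
``reach_ofc/configs/default.yaml``); code holds no magic numbers for noise or
cost magnitudes. A config hash is embedded in every artifact written by the
pipeline so runs can be audited.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ofc.cost import CostModel
from .ofc.noise import NoiseModel
from .ofc.plant import InvalidParameterError, PlantParams, SystemMatrices, build_discrete_system
from .ofc.simulate import TrialProtocol

SPEEDS = ("fast", "slow")
UNCERTAINTIES = ("low", "medium", "high", "inf")


class ConfigError(ValueError):
    """Raised for malformed or incomplete configuration files."""


@dataclass(frozen=True)
class SimulationConfig:
    plant: PlantParams
    noise: NoiseModel              # baseline (visual_scale applied per condition)
    visual_scales: dict[str, float]
    cost: CostModel
    movement_times: dict[str, float]
    target_distance: float = 0.20
    load: float = 9.0
    load_trigger_y: float = 0.005
    jump_sizes: tuple[float, ...] = (-0.02, 0.0, 0.02)
    jump_trigger_y: float = 0.08
    n_runs: int = 25
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -----------------------------------------------------
    @classmethod
    def default(cls) -> "SimulationConfig":
        with resources.files("reach_ofc.configs").joinpath("default.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        try:
            plant = PlantParams(**data["plant"])
            nd = dict(data["noise"])
            scales = {k: float(v) for k, v in nd.pop("visual_scales").items()}
            noise = NoiseModel(**nd)
            cost = CostModel(**data["cost"])
            prot = dict(data["protocol"])
            mts = {k: float(v) for k, v in prot.pop("movement_times").items()}
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid config: {exc}") from exc
        except InvalidParameterError as exc:
            raise ConfigError(f"invalid config parameter: {exc}") from exc
        missing = [u for u in UNCERTAINTIES if u not in scales]
        if missing:
            raise ConfigError(f"visual_scales missing conditions: {missing}")
        if any(s not in mts for s in SPEEDS):
            raise ConfigError(f"movement_times must define {SPEEDS}")
        return cls(plant=plant, noise=noise, visual_scales=scales, cost=cost,
                   movement_times=mts,
                   target_distance=float(prot.get("target_distance", 0.20)),
                   load=float(prot.get("load", 9.0)),
                   load_trigger_y=float(prot.get("load_trigger_y", 0.005)),
                   jump_sizes=tuple(float(j) for j in prot.get("jump_sizes", (-0.02, 0.0, 0.02))),
                   jump_trigger_y=float(prot.get("jump_trigger_y", 0.08)),
                   n_runs=int(prot.get("n_runs", 25)),
                   seed=int(data.get("seed", 0)),
                   raw=data)

    # -- factories --------------------------------------------------------
    def system(self) -> SystemMatrices:
        return build_discrete_system(self.plant)

    def noise_for(self, uncertainty: str) -> NoiseModel:
        if uncertainty not in self.visual_scales:
            raise ConfigError(f"unknown uncertainty condition {uncertainty!r}")
        return self.noise.with_visual_scale(self.visual_scales[uncertainty])

    def protocol_for(self, speed: str, jump_size: float = 0.0,
                     load: float | None = None) -> TrialProtocol:
        if speed not in self.movement_times:
            raise ConfigError(f"unknown speed condition {speed!r}")
        return TrialProtocol(movement_time=self.movement_times[speed],
                             target_distance=self.target_distance,
                             load=self.load if load is None else load,
                             load_trigger_y=self.load_trigger_y,
                             jump_size=jump_size,
                             jump_trigger_y=self.jump_trigger_y,
                             stab_duration=self.cost.stab_duration,
                             n_runs=self.n_runs)

    # -- provenance -------------------------------------------------------
    def hash(self) -> str:
        def _enc(o):
            if isinstance(o, float) and math.isinf(o):
                return "inf"
            raise TypeError
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=_enc).encode()).hexdigest()[:16]
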