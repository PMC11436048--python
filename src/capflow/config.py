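"""Experiment configuration: schema, validation, hashing.

One YAML/JSON config drives simulation, analysis and reporting.  Fluids and
devices may be preset names or inline definitions; everything is validated
field by field before any run, and a short SHA-256 hash of the canonical
config is stamped into every artifact so mismatches are detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from . import io
from .core_model import CapillaryGeometry, DeviceConfig, FluidProperties
from .errors import CapflowError, ConfigError
from .synthetic import NoiseModel, SamplingSchedule

DEFAULT_FLUIDS = ["water", "PRP", "WB"]
DEFAULT_DEVICES = ["straight-100", "loop1-150", "loop2-160"]


@dataclass
class ExperimentConfig:
    seed: int = 0
    fluids: list = field(default_factory=lambda: list(DEFAULT_FLUIDS))
    devices: list = field(default_factory=lambda: list(DEFAULT_DEVICES))
    geometry: dict = field(default_factory=lambda: {"bore_diameter_um": 200.0})
    schedule: dict = field(
        default_factory=lambda: {"t_start": 1.0, "t_end": 600.0, "interval": 1.0}
    )
    noise: dict = field(
        default_factory=lambda: {"sigma_H": 0.5, "sigma_t": 0.05, "replicate_cv": 0.0}
    )
    n_capillaries: int = 10
    analysis: dict = field(
        default_factory=lambda: {
            "window_inv_H": [0.0125, 0.06],
            "comparison_timepoint": 30.0,
        }
    )

    # ------------------------------------------------------------ validation

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        known = {
            "seed",
            "fluids",
            "devices",
            "geometry",
            "schedule",
            "noise",
            "n_capillaries",
            "analysis",
        }
        problems: List[str] = []
        for key in data:
            if key not in known:
                problems.append(f"{key}: unknown field")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        problems.extend(cfg._validate())
        if problems:
            raise ConfigError("invalid config:\n  " + "\n  ".join(problems))
        return cfg

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExperimentConfig":
        p = Path(path)
        with open(p) as fh:
            data = yaml.safe_load(fh) if p.suffix in {".yaml", ".yml"} else json.load(fh)
        return cls.from_dict(data or {})

    def _validate(self) -> List[str]:
        problems: List[str] = []
        if not isinstance(self.seed, int) or self.seed < 0:
            problems.append(f"seed: must be a non-negative integer, got {self.seed!r}")
        if not self.fluids:
            problems.append("fluids: must list at least one fluid")
        if not self.devices:
            problems.append("devices: must list at least one device")
        for resolver, label in [
            (self.resolve_fluids, "fluids"),
            (self.resolve_devices, "devices"),
            (self.resolve_geometry, "geometry"),
            (self.resolve_schedule, "schedule"),
            (self.resolve_noise, "noise"),
        ]:
            try:
                resolver()
            except (CapflowError, ValueError, TypeError, KeyError) as exc:
                problems.append(f"{label}: {exc}")
        if not isinstance(self.n_capillaries, int) or self.n_capillaries < 1:
            problems.append(f"n_capillaries: must be a positive integer, got {self.n_capillaries!r}")
        win = self.analysis.get("window_inv_H", [0.0125, 0.06])
        if not (isinstance(win, (list, tuple)) and len(win) == 2 and win[0] < win[1]):
            problems.append(f"analysis.window_inv_H: must be [lower, upper], got {win!r}")
        tp = self.analysis.get("comparison_timepoint", 30.0)
        if not (isinstance(tp, (int, float)) and tp > 0):
            problems.append(f"analysis.comparison_timepoint: must be > 0 s, got {tp!r}")
        return problems

    # ------------------------------------------------------------ resolution

    def resolve_fluids(self) -> Dict[str, FluidProperties]:
        presets = io.load_fluid_presets()
        out: Dict[str, FluidProperties] = {}
        for entry in self.fluids:
            if isinstance(entry, str):
                if entry not in presets:
                    raise ConfigError(
                        f"unknown fluid preset '{entry}' (known: {sorted(presets)})"
                    )
                out[entry] = presets[entry]
            elif isinstance(entry, dict) and "name" in entry:
                d = dict(entry)
                name = d.pop("name")
                out[name] = io.fluid_from_dict(name, d)
            else:
                raise ConfigError(f"fluid entry must be a preset name or mapping with 'name': {entry!r}")
        return out

    def resolve_devices(self) -> Dict[str, DeviceConfig]:
        presets = io.load_device_presets()
        out: Dict[str, DeviceConfig] = {}
        for entry in self.devices:
            if isinstance(entry, str):
                if entry not in presets:
                    raise ConfigError(
                        f"unknown device preset '{entry}' (known: {sorted(presets)})"
                    )
                out[entry] = presets[entry]
            elif isinstance(entry, dict) and "name" in entry:
                d = dict(entry)
                name = d.pop("name")
                out[name] = io.device_from_dict(name, d)
            else:
                raise ConfigError(f"device entry must be a preset name or mapping with 'name': {entry!r}")
        return out

    def resolve_geometry(self) -> CapillaryGeometry:
        g = self.geometry
        if "bore_diameter_um" in g:
            return CapillaryGeometry.circle(float(g["bore_diameter_um"]) * 1e-6)
        if "a_um" in g and "b_um" in g:
            return CapillaryGeometry(
                a=float(g["a_um"]) * 1e-6,
                b=float(g["b_um"]) * 1e-6,
                dh=float(g["dh_um"]) * 1e-6 if g.get("dh_um") is not None else None,
            )
        raise ConfigError(
            "geometry needs either bore_diameter_um or a_um and b_um"
        )

    def resolve_schedule(self) -> SamplingSchedule:
        s = self.schedule
        sched = SamplingSchedule(
            t_start=float(s.get("t_start", 1.0)),
            t_end=float(s.get("t_end", 600.0)),
            interval=float(s["interval"]) if s.get("interval") is not None else None,
            timepoints=s.get("timepoints"),
        )
        sched.times()  # raises on bad schedules
        return sched

    def resolve_noise(self) -> NoiseModel:
        n = self.noise
        return NoiseModel(
            sigma_H=float(n.get("sigma_H", 0.5)),
            sigma_t=float(n.get("sigma_t", 0.05)),
            replicate_cv=float(n.get("replicate_cv", 0.0)),
            seed=self.seed,
        )

    def window_inv_H(self):
        return tuple(self.analysis.get("window_inv_H", [0.0125, 0.06]))

    def comparison_timepoint(self) -> float:
        return float(self.analysis.get("comparison_timepoint", 30.0))

    # ------------------------------------------------------------ hashing

    def canonical_dict(self) -> dict:
        return {
            "seed": self.seed,
            "fluids": self.fluids,
            "devices": self.devices,
            "geometry": self.geometry,
            "schedule": self.schedule,
            "noise": self.noise,
            "n_capillaries": self.n_capillaries,
            "analysis": self.analysis,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.canonical_dict(), fh, sort_keys=True)
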