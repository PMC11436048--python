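"""Readers/writers for the package's plain-text formats.

- fluid/device presets and user definitions: YAML (or JSON) mappings
- observed/synthetic trajectory datasets: long-format CSV with columns
  strip_id, capillary_id, time_s, height_mm, length_mm
- analysis results and ground-truth sidecars: JSON
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core_model import CapillaryGeometry, DeviceConfig, FluidProperties, Trajectory
from .errors import ConfigError, InvalidTrajectoryError

DATASET_COLUMNS = ["strip_id", "capillary_id", "time_s", "height_mm", "length_mm"]


# ---------------------------------------------------------------- fluids


def _sig(x: float) -> float:
    """Round to 12 significant digits so lab-unit round trips are exact."""
    return float(f"{x:.12g}")


def fluid_to_dict(fluid: FluidProperties) -> dict:
    return {
        "rho_g_per_ml": _sig(fluid.rho_g_per_ml),
        "mu_cp": _sig(fluid.mu_cp),
        "gamma_cos_theta": fluid.gamma_cos_theta,
        "source": fluid.source,
    }


def fluid_from_dict(name: str, d: dict) -> FluidProperties:
    try:
        return FluidProperties.from_lab_units(
            name=name,
            rho_g_per_ml=float(d["rho_g_per_ml"]),
            mu_cp=float(d["mu_cp"]),
            gamma_cos_theta=(
                float(d["gamma_cos_theta"]) if d.get("gamma_cos_theta") is not None else None
            ),
            gamma=float(d["gamma"]) if d.get("gamma") is not None else None,
            theta_deg=float(d["theta_deg"]) if d.get("theta_deg") is not None else None,
            source=str(d.get("source", "user")),
        )
    except KeyError as exc:
        raise ConfigError(f"fluid '{name}': missing field {exc}") from exc


def device_to_dict(dev: DeviceConfig) -> dict:
    return {
        "strip_length_mm": dev.strip_length,
        "n_loops": dev.n_loops,
        "loop_length_mm": dev.loop_length,
        "loop_diameter_mm": dev.loop_diameter,
        "loop_entry_height_mm": dev.loop_entry_height,
        "vertical_extent_mm": dev.vertical_extent,
    }


def device_from_dict(name: str, d: dict) -> DeviceConfig:
    try:
        return DeviceConfig(
            name=name,
            strip_length=float(d["strip_length_mm"]),
            n_loops=int(d["n_loops"]),
            loop_length=float(d["loop_length_mm"]),
            loop_diameter=float(d.get("loop_diameter_mm", 0.0)),
            loop_entry_height=float(d.get("loop_entry_height_mm", 0.0)),
            vertical_extent=(
                float(d["vertical_extent_mm"]) if d.get("vertical_extent_mm") is not None else None
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"device '{name}': missing field {exc}") from exc


def _load_mapping(path_or_text: Union[str, Path]) -> dict:
    p = Path(path_or_text)
    with open(p) as fh:
        data = yaml.safe_load(fh) if p.suffix in {".yaml", ".yml"} else json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{p}: expected a mapping at top level")
    return data


def load_fluids(path: Union[str, Path]) -> Dict[str, FluidProperties]:
    return {name: fluid_from_dict(name, d) for name, d in _load_mapping(path).items()}


def load_devices(path: Union[str, Path]) -> Dict[str, DeviceConfig]:
    return {name: device_from_dict(name, d) for name, d in _load_mapping(path).items()}


def dump_fluids(fluids: Dict[str, FluidProperties], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({n: fluid_to_dict(f) for n, f in fluids.items()}, fh, sort_keys=True)


def dump_devices(devices: Dict[str, DeviceConfig], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({n: device_to_dict(d) for n, d in devices.items()}, fh, sort_keys=True)


def _preset_text(filename: str) -> str:
    return resources.files("capflow").joinpath(f"presets/{filename}").read_text()


def load_fluid_presets() -> Dict[str, FluidProperties]:
    data = yaml.safe_load(_preset_text("fluids.yaml"))
    return {name: fluid_from_dict(name, d) for name, d in data.items()}


def load_device_presets() -> Dict[str, DeviceConfig]:
    data = yaml.safe_load(_preset_text("devices.yaml"))
    return {name: device_from_dict(name, d) for name, d in data.items()}


# ---------------------------------------------------------------- datasets


def write_dataset(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a long-format trajectory dataset with stable float formatting
    (byte-identical output for identical inputs)."""
    df.to_csv(path, index=False, float_format="%.6f")


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a long-format trajectory CSV.

    Malformed rows are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidTrajectoryError(f"{path}: missing columns {missing}")
    bad = df.index[
        df[["time_s", "height_mm", "length_mm"]].isna().any(axis=1)
        | ~np.isfinite(df[["time_s", "height_mm", "length_mm"]]).all(axis=1)
    ]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise InvalidTrajectoryError(f"{path}: malformed rows at lines {lines}")
    return df


def dataset_to_trajectories(
    df: pd.DataFrame,
    devices: Optional[Dict[str, DeviceConfig]] = None,
    fluids: Optional[Dict[str, FluidProperties]] = None,
) -> List[Trajectory]:
    """Split a long-format dataset into per-capillary trajectories.

    Strip ids of the form ``fluid@device`` are resolved against the given
    maps when provided; otherwise device/fluid references stay None (fine
    for observed data)."""
    out: List[Trajectory] = []
    for (sid, cid), grp in df.groupby(["strip_id", "capillary_id"], sort=True):
        grp = grp.sort_values("time_s")
        device = fluid = None
        if "@" in str(sid):
            fname, dname = str(sid).split("@", 1)
            if fluids is not None:
                fluid = fluids.get(fname)
            if devices is not None:
                device = devices.get(dname)
        out.append(
            Trajectory(
                strip_id=str(sid),
                capillary_id=int(cid),
                t=grp["time_s"].to_numpy(),
                H=grp["height_mm"].to_numpy(),
                L=grp["length_mm"].to_numpy(),
                device=device,
                fluid=fluid,
            )
        )
    return out


def write_json(obj: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)
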