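"""Synthetic trajectory generator.

Emulates the statistical structure of time-lapse capillary-rise data: 10
replicate capillaries per strip, fixed-interval sampling with timestamp
jitter, additive height-measurement noise, optional capillary-to-capillary
scatter of the surface parameter, and a phenomenological viscosity ramp
standing in for stimulated coagulation.  Every stream is counter-based
(Philox keyed by seed and capillary index) so the same seed and
configuration reproduce a dataset bit for bit and adding capillaries does
not shift the other streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import io, units
from .core_model import (
    CapillaryGeometry,
    DeviceConfig,
    FluidProperties,
    ModelSettings,
    Trajectory,
    _front_to_HL,
    _k,
    capillary_pressure,
    integrate_rise,
)
from .errors import InvalidProfileError, InvalidScheduleError

__all__ = [
    "NoiseModel",
    "SamplingSchedule",
    "StimulationProfile",
    "fluid_presets",
    "device_presets",
    "simulate_strip",
    "simulate_experiment",
    "stimulated_viscosity_trajectory",
    "stalled_in_loop",
]

_DEFAULT_SETTINGS = ModelSettings()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic strips.

    sigma_H: additive height noise SD (mm) -- image-annotation scatter.
    sigma_t: timestamp jitter SD (s) -- image-capture timing scatter.
    replicate_cv: coefficient of variation of gamma_cos_theta across the
        capillaries of one strip (bore/coating variability); off by default.
    seed: integer stream key; identical seed + config gives bitwise-
        identical output.
    """

    sigma_H: float = 0.5
    sigma_t: float = 0.05
    replicate_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_H < 0 or self.sigma_t < 0 or self.replicate_cv < 0:
            raise ValueError("noise SDs and replicate_cv must be >= 0")

    def zero(self) -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, self.seed)


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling times: fixed interval on [t_start, t_end] or explicit list."""

    t_start: float = 1.0
    t_end: float = 600.0
    interval: Optional[float] = 1.0
    timepoints: Optional[Sequence[float]] = None

    def times(self) -> np.ndarray:
        if self.timepoints is not None:
            t = np.asarray(self.timepoints, dtype=float)
        else:
            if self.interval is None or self.interval <= 0:
                raise InvalidScheduleError("interval must be > 0")
            n = int(math.floor((self.t_end - self.t_start) / self.interval + 1e-9)) + 1
            t = self.t_start + self.interval * np.arange(n)
        if t.ndim != 1 or len(t) == 0:
            raise InvalidScheduleError("schedule must contain at least one timepoint")
        if t[0] < 0 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise InvalidScheduleError("timepoints must be >= 0 and strictly increasing")
        return t


@dataclass(frozen=True)
class StimulationProfile:
    """Phenomenological viscosity ramp mimicking stimulated coagulation.

    mu(t) = mu_baseline                      for t < onset_time
          = min(mu_max, mu_baseline + ramp_rate*(t - onset_time))  after.

    This is a qualitative stand-in for agonist-triggered clotting (no
    mechanistic kinetics); all values in cP, ramp_rate in cP/s.
    """

    mu_baseline: float
    mu_max: float
    onset_time: float = 0.0
    ramp_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_baseline <= 0:
            raise InvalidProfileError("mu_baseline must be > 0 cP")
        if self.mu_max < self.mu_baseline:
            raise InvalidProfileError("mu_max must be >= mu_baseline")
        if self.ramp_rate < 0:
            raise InvalidProfileError("ramp_rate must be >= 0")

    def mu_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ramp = self.mu_baseline + self.ramp_rate * np.maximum(0.0, t - self.onset_time)
        return np.minimum(self.mu_max, ramp)


# ---------------------------------------------------------------- presets


def fluid_presets() -> Dict[str, FluidProperties]:
    """Named fluid presets (water/PRP/WB literature values; HBS/PPP/RBC
    documented assumptions, flagged via their ``source`` field)."""
    return io.load_fluid_presets()


def device_presets() -> Dict[str, DeviceConfig]:
    """Named strip layouts: straight-100, loop1-150 (43 mm looped region),
    loop2-160 (58 mm looped region)."""
    return io.load_device_presets()


# ---------------------------------------------------------------- generators


def _capillary_rng(seed: int, stream_key: Tuple[int, ...], capillary: int) -> np.random.Generator:
    """Counter-based stream: Philox keyed by (seed, *stream_key, capillary)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(*stream_key, capillary))
    return np.random.Generator(np.random.Philox(ss))


def _jitter_times(t: np.ndarray, rng: np.random.Generator, sigma_t: float) -> np.ndarray:
    if sigma_t <= 0:
        return t
    tj = t + rng.normal(0.0, sigma_t, size=len(t))
    tj = np.maximum(tj, 0.0)
    tj.sort()
    # enforce strict monotonicity after clipping/sorting
    for i in range(1, len(tj)):
        if tj[i] <= tj[i - 1]:
            tj[i] = tj[i - 1] + 1e-9
    return tj


def simulate_strip(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: DeviceConfig,
    schedule: SamplingSchedule,
    noise: NoiseModel,
    n_capillaries: int = 10,
    strip_id: Optional[str] = None,
    settings: Optional[ModelSettings] = None,
    stream_key: Tuple[int, ...] = (),
) -> List[Trajectory]:
    """Simulate one strip: ``n_capillaries`` replicate noisy trajectories.

    Per capillary: draw a gamma_cos_theta multiplier (lognormal with the
    requested CV), integrate the noiseless model, sample it at jittered
    times, add height noise, and clamp H to [0, vertical_extent].  With all
    noise parameters zero each capillary equals the noiseless
    :func:`integrate_rise` output exactly.
    """
    settings = settings or _DEFAULT_SETTINGS
    sid = strip_id or f"{fluid.name}@{device.name}"
    t_nominal = schedule.times()
    out: List[Trajectory] = []
    for cap in range(n_capillaries):
        rng = _capillary_rng(noise.seed, stream_key, cap)
        z = rng.standard_normal()  # always consumed: stream layout is fixed
        if noise.replicate_cv > 0:
            sig = math.sqrt(math.log1p(noise.replicate_cv**2))
            mult = math.exp(sig * z - 0.5 * sig**2)
        else:
            mult = 1.0
        fl = fluid.with_gamma_cos_theta(fluid.gamma_cos_theta * mult, source=fluid.source)
        tj = _jitter_times(t_nominal, rng, noise.sigma_t)
        base = integrate_rise(fl, geom, device, settings, tj)
        H = base.H
        if noise.sigma_H > 0:
            H = H + rng.normal(0.0, noise.sigma_H, size=len(H))
            H = np.clip(H, 0.0, device.vertical_extent)
        if device.loop_length > 0:
            passed = base.H >= device.loop_entry_height
            L = np.where(passed, H + device.loop_length, H)
        else:
            L = H.copy()
        out.append(
            Trajectory(
                strip_id=sid,
                capillary_id=cap,
                t=tj,
                H=H,
                L=L,
                device=device,
                fluid=fl,
                reached_top=base.reached_top,
            )
        )
    return out


def simulate_experiment(config) -> Tuple[pd.DataFrame, dict]:
    """Simulate a full fluids x devices design from an ExperimentConfig.

    Returns the long-format dataset (one row per capillary per timepoint)
    and a ground-truth sidecar recording every generating parameter, for
    parameter-recovery testing.
    """
    geom = config.resolve_geometry()
    fluids = config.resolve_fluids()
    devices = config.resolve_devices()
    schedule = config.resolve_schedule()
    noise = config.resolve_noise()
    frames: List[pd.DataFrame] = []
    strips: Dict[str, dict] = {}
    strip_index = 0
    for fname, fluid in fluids.items():
        for dname, device in devices.items():
            sid = f"{fname}@{dname}"
            trajs = simulate_strip(
                fluid,
                geom,
                device,
                schedule,
                noise,
                n_capillaries=config.n_capillaries,
                strip_id=sid,
                stream_key=(strip_index,),
            )
            frames.extend(tr.to_dataframe() for tr in trajs)
            strips[sid] = {
                "fluid": fname,
                "device": dname,
                "fluid_properties": io.fluid_to_dict(fluid),
                "device_config": io.device_to_dict(device),
                "gamma_cos_theta_true": [tr.fluid.gamma_cos_theta for tr in trajs],
                "mu_cp_true": fluid.mu_cp,
            }
            strip_index += 1
    df = pd.concat(frames, ignore_index=True)
    sidecar = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rng": "numpy Philox, SeedSequence(seed, spawn_key=(strip, capillary))",
        "geometry": {"a_m": geom.a, "b_m": geom.b, "dh_m": geom.dh},
        "schedule": {
            "t_start": schedule.t_start,
            "t_end": schedule.t_end,
            "interval": schedule.interval,
            "timepoints": list(schedule.timepoints) if schedule.timepoints else None,
        },
        "noise": {
            "sigma_H": noise.sigma_H,
            "sigma_t": noise.sigma_t,
            "replicate_cv": noise.replicate_cv,
            "seed": noise.seed,
        },
        "n_capillaries": config.n_capillaries,
        "strips": strips,
    }
    return df, sidecar


def stimulated_viscosity_trajectory(
    fluid: FluidProperties,
    profile: StimulationProfile,
    geom: CapillaryGeometry,
    device: DeviceConfig,
    schedule: SamplingSchedule,
    noise: Optional[NoiseModel] = None,
    settings: Optional[ModelSettings] = None,
    capillary_id: int = 0,
) -> Trajectory:
    """Quasi-steady rise with a time-dependent viscosity ramp.

    Integrates the front position ell along the strip,
    d(ell)/dt = k(t) (P0 - rho g z(ell)) / ell, with the meniscus elevation
    z piecewise in ell (vertical before the loop entry, held at the entry
    height inside the loop, ell - loop_length after) and
    k(t) = dh^2 / (32 mu(t)).  Steeper/higher ramps give lower heights at
    every time after onset; a ramp steep enough that the front never exits
    the looped region reproduces the could-not-pass-the-loop regime (see
    :func:`stalled_in_loop`).
    """
    settings = settings or _DEFAULT_SETTINGS
    t = schedule.times()
    p0 = capillary_pressure(fluid, geom)
    rho_g = fluid.rho * settings.g
    h_eq_m = p0 / rho_g
    dh2_32 = geom.dh**2 / 32.0
    e_m = units.mm_to_m(device.loop_entry_height)
    lp_m = units.mm_to_m(device.loop_length)
    extent_m = units.mm_to_m(device.vertical_extent)
    ell0 = units.mm_to_m(settings.H0)
    ell_stop = lp_m + min((1.0 - settings.eps_eq) * h_eq_m, extent_m)

    def z_of(ell: float) -> float:
        if lp_m == 0.0 or ell <= e_m:
            return ell
        if ell < e_m + lp_m:
            return e_m
        return ell - lp_m

    def rhs(tt, y):
        mu = units.cp_to_pa_s(float(profile.mu_at(tt)))
        return [(dh2_32 / mu) * (p0 - rho_g * z_of(y[0])) / y[0]]

    def stop(_tt, y):
        return y[0] - ell_stop

    stop.terminal = True
    stop.direction = 1.0

    if t[-1] == 0.0:
        ell = np.array([ell0])
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(t[-1])),
            [ell0],
            method="LSODA",
            t_eval=t,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            events=stop,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"stimulated rise integration failed: {sol.message}")
        ys = np.asarray(sol.y)
        ell = ys[0] if ys.size else np.empty(0)
        if len(ell) < len(t):
            ell = np.concatenate([ell, np.full(len(t) - len(ell), ell_stop)])
        ell = np.minimum(ell, ell_stop)

    ell_mm = units.m_to_mm(ell)
    H_mm, L_mm = _front_to_HL(ell_mm, device)
    if noise is not None and noise.sigma_H > 0:
        rng = _capillary_rng(noise.seed, (), capillary_id)
        H_mm = np.clip(
            H_mm + rng.normal(0.0, noise.sigma_H, size=len(H_mm)),
            0.0,
            device.vertical_extent,
        )
    return Trajectory(
        strip_id=f"{fluid.name}@{device.name}+stim",
        capillary_id=capillary_id,
        t=t,
        H=H_mm,
        L=L_mm,
        device=device,
        fluid=fluid,
    )


def stalled_in_loop(traj: Trajectory) -> bool:
    """True when the final front position is still inside the looped region."""
    if traj.device is None or traj.device.loop_length == 0:
        return False
    e = traj.device.loop_entry_height
    return bool(e < traj.L[-1] < e + traj.device.loop_length)
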