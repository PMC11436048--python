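"""Trajectory analysis: finite-difference velocity profiling, reciprocal-
height windowing, model overlays, surface/viscosity fitting and replicate
group statistics.

The analysis chain mirrors how time-lapse capillary-rise data are reduced:
heights from sequential image pairs become finite-difference velocities,
which for a straight strip should fall on the affine line
``v = (k P0) (1/H) - k rho g`` -- so velocity is profiled against the
reciprocal height 1/H, the model curve is overlaid, and surface parameters
(from equilibrium heights) or viscosity (from the velocity profile) are
fitted.  Replicate groups (straight vs looped strips) are compared with
one-way ANOVA and Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from . import units
from .core_model import (
    CapillaryGeometry,
    DeviceConfig,
    FluidProperties,
    ModelSettings,
    Trajectory,
    _k,
    capillary_pressure,
    equilibrium_height,
    estimate_gamma_cos_theta,
    instantaneous_velocity,
)
from .errors import (
    DegenerateDataError,
    InvalidObservationError,
    InvalidTrajectoryError,
    UnfittableProfileError,
)

__all__ = [
    "VelocityProfile",
    "SurfaceFit",
    "ViscosityFit",
    "GroupComparison",
    "finite_difference_velocity",
    "reciprocal_window_filter",
    "height_window",
    "predict_velocity_curve",
    "estimate_surface_params",
    "fit_viscosity",
    "one_way_anova",
    "tukey_hsd",
    "shapiro_wilk",
    "compare_groups",
]

_DEFAULT_SETTINGS = ModelSettings()

#: reciprocal-height analysis window (1/mm) used for late-time profiling
DEFAULT_WINDOW_INV_H = (0.0125, 0.06)


@dataclass
class VelocityProfile:
    """(height, 1/height, velocity) triples from data or from the model.

    ``H_mid``/``t_mid`` are the midpoints of consecutive sample pairs for
    observed profiles; for predicted profiles they are the evaluation grid
    and ``t_mid`` is NaN.
    """

    H_mid: np.ndarray
    inv_H: np.ndarray
    v: np.ndarray
    t_mid: np.ndarray
    source: str = "observed"
    height_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.H_mid = np.asarray(self.H_mid, dtype=float)
        self.inv_H = np.asarray(self.inv_H, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.t_mid = np.asarray(self.t_mid, dtype=float)

    def __len__(self) -> int:
        return len(self.H_mid)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "H_mid_mm": self.H_mid,
                "inv_H_per_mm": self.inv_H,
                "v_mm_s": self.v,
                "t_mid_s": self.t_mid,
            }
        )


@dataclass
class SurfaceFit:
    """Surface-parameter estimate from straight-strip equilibrium heights."""

    fluid_name: str
    gamma_cos_theta_hat: float
    equilibria: np.ndarray
    sd_height: float
    sd_gamma_cos_theta: float

    @property
    def n_replicates(self) -> int:
        return len(self.equilibria)


@dataclass
class ViscosityFit:
    """Viscosity estimate (cP) from a velocity profile."""

    mu_cp: float
    residual_norm: float
    n_points: int


@dataclass
class GroupComparison:
    """One-way ANOVA across replicate groups with optional Tukey HSD table."""

    labels: list
    ns: list
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: Optional[pd.DataFrame] = None
    normality: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "labels": list(self.labels),
            "n_per_group": [int(n) for n in self.ns],
            "F": float(self.F),
            "df_between": int(self.df_between),
            "df_within": int(self.df_within),
            "p_value": float(self.p_value),
        }
        if self.tukey is not None:
            out["tukey"] = self.tukey.to_dict(orient="records")
        if self.normality is not None:
            out["shapiro_wilk"] = {
                k: {"W": float(w), "p_value": float(p)}
                for k, (w, p) in self.normality.items()
            }
        return out


# --------------------------------------------------------------------------
# velocity profiling
# --------------------------------------------------------------------------


def finite_difference_velocity(traj: Trajectory) -> VelocityProfile:
    """Velocity profile v = dH/dt from consecutive sample pairs.

    Each pair contributes one point at the midpoint height and time; the
    midpoint assignment makes the estimate second-order accurate in the
    sampling interval.  Time differences come from the actual timestamps.
    """
    if len(traj) < 2:
        raise InvalidTrajectoryError("need at least two samples for velocities")
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise InvalidTrajectoryError("duplicate or non-increasing timestamps")
    dH = np.diff(traj.H)
    H_mid = 0.5 * (traj.H[:-1] + traj.H[1:])
    t_mid = 0.5 * (traj.t[:-1] + traj.t[1:])
    with np.errstate(divide="ignore"):
        inv_H = np.where(H_mid > 0, 1.0 / np.where(H_mid > 0, H_mid, 1.0), np.inf)
    return VelocityProfile(H_mid=H_mid, inv_H=inv_H, v=dH / dt, t_mid=t_mid)


def height_window(window_inv_H: Sequence[float]) -> Tuple[float, float]:
    """Convert a reciprocal-height window (1/mm) to the height window (mm).

    [lo, hi] in 1/mm maps to (1/hi, 1/lo) mm: e.g. [0.0125, 0.06] 1/mm is
    heights of about 16.7-80 mm.
    """
    lo, hi = window_inv_H
    if not lo < hi:
        raise InvalidObservationError(f"window must satisfy lower < upper, got {window_inv_H}")
    return (1.0 / hi, 1.0 / lo)


def reciprocal_window_filter(
    profile: VelocityProfile, window_inv_H: Sequence[float] = DEFAULT_WINDOW_INV_H
) -> VelocityProfile:
    """Retain points whose 1/H lies inside the closed reciprocal window.

    The kept profile carries the equivalent height window; an empty result
    is a warning, not an error (late-time data may simply not exist yet).
    """
    lo, hi = window_inv_H
    hw = height_window(window_inv_H)
    mask = (profile.inv_H >= lo) & (profile.inv_H <= hi)
    if not mask.any():
        warnings.warn(
            f"no profile points inside the 1/H window [{lo}, {hi}] 1/mm",
            stacklevel=2,
        )
    return VelocityProfile(
        H_mid=profile.H_mid[mask],
        inv_H=profile.inv_H[mask],
        v=profile.v[mask],
        t_mid=profile.t_mid[mask],
        source=profile.source,
        height_window=hw,
    )


def predict_velocity_curve(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: Optional[DeviceConfig] = None,
    H_grid: Sequence[float] = (),
    settings: Optional[ModelSettings] = None,
) -> VelocityProfile:
    """Model velocity profile on a height grid (mm), for overlay on data.

    For straight devices the (1/H, v) points lie exactly on the affine line
    with slope k*P0 and intercept -k*rho*g.
    """
    settings = settings or _DEFAULT_SETTINGS
    H = np.asarray(H_grid, dtype=float)
    h_eq = equilibrium_height(fluid, geom, settings)
    if np.any(H <= 0) or np.any(H >= h_eq):
        raise InvalidObservationError(
            f"H_grid must lie strictly inside (0, H_eq={h_eq:.3f}) mm"
        )
    v = instantaneous_velocity(H, fluid, geom, device, settings)
    return VelocityProfile(
        H_mid=H, inv_H=1.0 / H, v=v, t_mid=np.full_like(H, np.nan), source="predicted"
    )


# --------------------------------------------------------------------------
# parameter fitting
# --------------------------------------------------------------------------


def estimate_surface_params(
    equilibria: Sequence[float],
    rho: float,
    geom: CapillaryGeometry,
    fluid_name: str = "",
    settings: Optional[ModelSettings] = None,
) -> SurfaceFit:
    """Estimate gamma*cos(theta) from per-replicate equilibrium heights (mm).

    The estimate inverts the mean equilibrium height; the replicate SD is
    propagated through the (linear) inversion.  Observations must come from
    straight strips, where the equilibrium is measured directly -- by
    loop-invariance the estimate then applies to looped strips too.
    """
    settings = settings or _DEFAULT_SETTINGS
    eq = np.asarray(equilibria, dtype=float)
    if eq.ndim != 1 or len(eq) < 1:
        raise InvalidObservationError("need at least one equilibrium observation")
    if np.any(eq <= 0):
        raise InvalidObservationError("equilibrium heights must be > 0 mm")
    ghat = estimate_gamma_cos_theta(float(eq.mean()), rho, geom, settings)
    sd_h = float(eq.std(ddof=1)) if len(eq) > 1 else 0.0
    # linear map: d(gamma cos theta)/dH = rho g / (1/a + 1/b)
    sd_g = rho * settings.g * units.mm_to_m(sd_h) / (1.0 / geom.a + 1.0 / geom.b)
    return SurfaceFit(
        fluid_name=fluid_name,
        gamma_cos_theta_hat=ghat,
        equilibria=eq,
        sd_height=sd_h,
        sd_gamma_cos_theta=sd_g,
    )


def fit_viscosity(
    profile: VelocityProfile,
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: Optional[DeviceConfig] = None,
    settings: Optional[ModelSettings] = None,
    bounds_cp: Tuple[float, float] = (0.01, 1000.0),
) -> ViscosityFit:
    """Fit dynamic viscosity (cP) to an observed velocity profile.

    rho and gamma*cos(theta) are taken as known from ``fluid``; the only
    free parameter is mu.  Bounded scalar least squares on velocity-space
    residuals (heights carry the measurement noise, so residuals are taken
    in v, not in 1/H).  Points at or above the equilibrium height carry no
    viscosity information and are excluded.
    """
    settings = settings or _DEFAULT_SETTINGS
    h_eq = equilibrium_height(fluid, geom, settings)
    mask = (profile.H_mid > 0) & (profile.H_mid < h_eq) & np.isfinite(profile.v)
    if not mask.any():
        raise UnfittableProfileError(
            "all profile points lie at or above the equilibrium height"
        )
    if mask.sum() < 3:
        raise UnfittableProfileError(
            f"need >= 3 usable points below equilibrium, got {int(mask.sum())}"
        )
    H = profile.H_mid[mask]
    v_obs = profile.v[mask]

    def ssr(mu_cp: float) -> float:
        trial = fluid.with_mu(units.cp_to_pa_s(mu_cp))
        v_mod = instantaneous_velocity(H, trial, geom, device, settings)
        r = v_mod - v_obs
        return float(r @ r)

    res = minimize_scalar(
        ssr, bounds=bounds_cp, method="bounded", options={"xatol": 1e-8}
    )
    return ViscosityFit(
        mu_cp=float(res.x),
        residual_norm=float(np.sqrt(res.fun)),
        n_points=int(mask.sum()),
    )


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------


def _as_groups(groups) -> Tuple[list, list]:
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise DegenerateDataError("need at least two groups")
    for lab, arr in zip(labels, arrays):
        if arr.ndim != 1 or len(arr) < 2:
            raise DegenerateDataError(f"group '{lab}' needs at least two values")
    return labels, arrays


def one_way_anova(groups) -> GroupComparison:
    """One-way fixed-effects ANOVA via the SSB/SSW decomposition.

    ``groups`` is a mapping label -> values or a sequence of value arrays.
    F = MSB/MSW with df (k-1, N-k); the p-value comes from the F
    distribution.  Zero within-group variance is degenerate (F undefined).
    """
    labels, arrays = _as_groups(groups)
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ssw <= 0:
        raise DegenerateDataError("zero within-group variance; F is undefined")
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return GroupComparison(
        labels=labels,
        ns=[len(a) for a in arrays],
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
    )


def tukey_hsd(groups) -> pd.DataFrame:
    """All pairwise mean differences with studentized-range adjusted p-values.

    Delegates to the standard Tukey HSD routine; returns one row per
    unordered pair (k*(k-1)/2 rows) with the difference of means and the
    family-wise adjusted p-value.
    """
    labels, arrays = _as_groups(groups)
    if sum(((a - a.mean()) ** 2).sum() for a in arrays) <= 0:
        raise DegenerateDataError("zero within-group variance; q is undefined")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(np.clip(res.pvalue[i, j], 0.0, 1.0)),
                }
            )
    return pd.DataFrame(rows)


def shapiro_wilk(values) -> Tuple[float, float]:
    """Shapiro-Wilk normality statistic and p-value (reported, gates nothing)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


def compare_groups(groups) -> GroupComparison:
    """ANOVA + Tukey HSD + per-group Shapiro-Wilk in one result object."""
    labels, arrays = _as_groups(groups)
    comp = one_way_anova(dict(zip(labels, arrays)))
    comp.tukey = tukey_hsd(dict(zip(labels, arrays)))
    comp.normality = {
        lab: shapiro_wilk(arr) if len(arr) >= 3 else (float("nan"), float("nan"))
        for lab, arr in zip(labels, arrays)
    }
    return comp
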