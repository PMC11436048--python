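"""Pressure-balance model of capillary rise in microcapillary film strips.

The model balances the Laplace (wetting) pressure drawing liquid into a
narrow elliptical bore against the hydrostatic head of the risen column and
Poiseuille-type viscous friction along the wetted length.  For a straight
vertical strip the wetted length equals the meniscus height ``H``, giving
the quasi-steady velocity law

    dH/dt = (dh^2 / 32 mu) * [ (1/a + 1/b) gamma cos(theta) - rho g H ] / H

with semi-axes ``a, b`` of the elliptical cross-section and hydraulic
diameter ``dh``.  Coiling an extra loop of path length ``L_loop`` near the
inlet lengthens the friction path to ``H + L_loop`` without altering the
equilibrium balance:

    dH/dt = (dh^2 / 32 mu) * [ (1/a + 1/b) gamma cos(theta) - rho g H ] / (H + L_loop)

This is the design principle behind looped "dip-and-test" strips: slower
flow and longer stimulus residence time at an unchanged equilibrium height
``H_eq = P0 / (rho g)``.

Units: SI internally; public interfaces use mm, s, cP and g/mL with all
conversions centralised in :mod:`capflow.units`.  Only the product
``gamma cos(theta)`` is identifiable from an equilibrium height, so the
model is parameterised by that product; separate ``gamma`` and ``theta``
are accepted and reduced to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import PchipInterpolator

from . import units
from .errors import (
    InvalidDeviceError,
    InvalidFluidError,
    InvalidGeometryError,
    InvalidObservationError,
    InvalidScheduleError,
    InvalidTrajectoryError,
    SingularInputError,
    StalledFrontError,
    UnreachableHeightError,
)

__all__ = [
    "FluidProperties",
    "CapillaryGeometry",
    "DeviceConfig",
    "ModelSettings",
    "Trajectory",
    "capillary_pressure",
    "hydraulic_diameter",
    "ellipse_perimeter_ramanujan",
    "equilibrium_height",
    "estimate_gamma_cos_theta",
    "instantaneous_velocity",
    "integrate_rise",
    "time_to_height",
    "loop_residence_time",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Bulk and surface properties of a sample liquid.

    Parameters
    ----------
    name:
        Label ("water", "PRP", "WB", ...).
    rho:
        Density in kg/m^3.
    mu:
        Dynamic viscosity in Pa s.
    gamma_cos_theta:
        Product of surface tension (N/m) and the cosine of the contact
        angle -- the only surface quantity the equilibrium height can
        identify.  Derived from ``gamma`` and ``theta`` when those are
        given instead.
    gamma, theta:
        Optional separate surface tension (N/m) and contact angle
        (degrees).  When both are present together with
        ``gamma_cos_theta`` they must agree to 1e-12 N/m.
    source:
        Provenance tag ("printed", "calibrated", "assumed", "user").
    """

    name: str
    rho: float
    mu: float
    gamma_cos_theta: Optional[float] = None
    gamma: Optional[float] = None
    theta: Optional[float] = None
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise InvalidFluidError(f"rho must be > 0, got {self.rho}")
        if not self.mu > 0:
            raise InvalidFluidError(f"mu must be > 0, got {self.mu}")
        if self.gamma_cos_theta is None:
            if self.gamma is None or self.theta is None:
                raise InvalidFluidError(
                    "either gamma_cos_theta or both gamma and theta are required"
                )
            object.__setattr__(
                self,
                "gamma_cos_theta",
                self.gamma * math.cos(math.radians(self.theta)),
            )
        elif self.gamma is not None and self.theta is not None:
            derived = self.gamma * math.cos(math.radians(self.theta))
            if abs(derived - self.gamma_cos_theta) > 1e-12:
                raise InvalidFluidError(
                    "gamma*cos(theta) inconsistent with gamma_cos_theta: "
                    f"{derived!r} vs {self.gamma_cos_theta!r}"
                )
        if self.gamma_cos_theta < 0:
            raise InvalidFluidError(
                f"gamma_cos_theta must be >= 0, got {self.gamma_cos_theta}"
            )

    @classmethod
    def from_lab_units(
        cls,
        name: str,
        rho_g_per_ml: float,
        mu_cp: float,
        gamma_cos_theta: Optional[float] = None,
        gamma: Optional[float] = None,
        theta_deg: Optional[float] = None,
        source: str = "user",
    ) -> "FluidProperties":
        """Build from g/mL density and cP viscosity."""
        return cls(
            name=name,
            rho=units.g_ml_to_kg_m3(rho_g_per_ml),
            mu=units.cp_to_pa_s(mu_cp),
            gamma_cos_theta=gamma_cos_theta,
            gamma=gamma,
            theta=theta_deg,
            source=source,
        )

    @property
    def rho_g_per_ml(self) -> float:
        return self.rho * units.G_ML_PER_KG_M3

    @property
    def mu_cp(self) -> float:
        return self.mu * units.CP_PER_PA_S

    def with_gamma_cos_theta(self, value: float, source: str = "calibrated") -> "FluidProperties":
        """Copy of this fluid with a new surface parameter."""
        return replace(self, gamma_cos_theta=value, gamma=None, theta=None, source=source)

    def with_mu(self, mu: float) -> "FluidProperties":
        """Copy of this fluid with a new viscosity (Pa s)."""
        return replace(self, mu=mu)


def ellipse_perimeter_ramanujan(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a, b (Ramanujan's second form).

    Accurate to ~1e-9 relative even at high eccentricity; exact for a = b.
    """
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


@dataclass(frozen=True)
class CapillaryGeometry:
    """Elliptical cross-section of one capillary bore.

    ``a`` and ``b`` are the SEMI-major and SEMI-minor axes in metres, so the
    circular limit a = b = r reproduces the Laplace pressure 2*gamma*cos(theta)/r.
    ``dh`` is the hydraulic diameter 4*area/perimeter; it may be supplied
    directly (e.g. from microscopy) or is derived with Ramanujan's perimeter
    approximation.  For a circle ``dh = 2a`` exactly.
    """

    a: float
    b: float
    dh: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.a > 0):
            raise InvalidGeometryError(
                f"semi-axes must be positive, got a={self.a}, b={self.b}"
            )
        if self.b > self.a:
            raise InvalidGeometryError(
                f"semi-minor axis b={self.b} exceeds semi-major axis a={self.a}"
            )
        if self.dh is None:
            if self.a == self.b:
                dh = 2.0 * self.a
            else:
                area = math.pi * self.a * self.b
                dh = 4.0 * area / ellipse_perimeter_ramanujan(self.a, self.b)
            object.__setattr__(self, "dh", dh)
        elif not self.dh > 0:
            raise InvalidGeometryError(f"dh must be > 0, got {self.dh}")

    @classmethod
    def circle(cls, diameter: float = 200e-6) -> "CapillaryGeometry":
        """Circular bore of the given internal diameter (m); default 200 um."""
        r = diameter / 2.0
        return cls(a=r, b=r)


@dataclass(frozen=True)
class DeviceConfig:
    """One test-strip layout: total length, loop region, measurable extent.

    All lengths in mm.  ``loop_length`` is the TOTAL extra path length of
    the looped region (0 for straight strips); ``loop_entry_height`` is the
    elevation of the loop region above the reservoir surface, used only by
    residence-time and stimulated-front calculations.
    """

    name: str
    strip_length: float
    n_loops: int
    loop_length: float
    loop_diameter: float = 0.0
    loop_entry_height: float = 0.0
    vertical_extent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_loops not in (0, 1, 2):
            raise InvalidDeviceError(f"n_loops must be 0, 1 or 2, got {self.n_loops}")
        if self.loop_length < 0:
            raise InvalidDeviceError(f"loop_length must be >= 0, got {self.loop_length}")
        if self.n_loops == 0 and self.loop_length != 0:
            raise InvalidDeviceError("straight device (n_loops=0) must have loop_length=0")
        if self.n_loops > 0 and self.loop_length <= 0:
            raise InvalidDeviceError("looped device must have loop_length > 0")
        if self.vertical_extent is None:
            object.__setattr__(self, "vertical_extent", self.strip_length - self.loop_length)
        if self.vertical_extent > self.strip_length - self.loop_length:
            raise InvalidDeviceError(
                "vertical_extent exceeds strip_length - loop_length "
                f"({self.vertical_extent} > {self.strip_length - self.loop_length})"
            )
        if self.loop_entry_height + self.loop_diameter > self.vertical_extent:
            raise InvalidDeviceError(
                "loop_entry_height + loop_diameter exceeds vertical_extent"
            )
        if self.loop_entry_height < 0:
            raise InvalidDeviceError("loop_entry_height must be >= 0")

    @classmethod
    def straight(cls, strip_length: float = 100.0, name: str = "straight") -> "DeviceConfig":
        return cls(name=name, strip_length=strip_length, n_loops=0, loop_length=0.0)


@dataclass(frozen=True)
class ModelSettings:
    """Numerical settings for trajectory integration.

    ``H0`` (mm) is the starting height: the velocity law is singular at
    H = 0 for straight strips, so integration begins just above the
    reservoir.  ``eps_eq`` sets the saturation clamp: integration stops once
    H reaches (1 - eps_eq) * H_eq and the trajectory is held there.
    """

    g: float = units.STANDARD_GRAVITY
    H0: float = 0.1
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    eps_eq: float = 1e-6

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if not self.H0 > 0:
            raise ValueError(f"H0 must be > 0, got {self.H0}")
        if not (self.rel_tol > 0 and self.abs_tol > 0 and self.eps_eq > 0):
            raise ValueError("tolerances must be > 0")


_DEFAULT_SETTINGS = ModelSettings()


@dataclass
class Trajectory:
    """Per-capillary timeseries of meniscus height H and wetted length L.

    ``t`` in s, ``H`` and ``L`` in mm.  For model output H is
    non-decreasing; observed (noisy) trajectories need not be.  L equals the
    front position along the strip before the loop and H + loop_length once
    the front has passed it (L = H for straight strips).
    """

    strip_id: str
    capillary_id: int
    t: np.ndarray
    H: np.ndarray
    L: np.ndarray
    device: Optional[DeviceConfig] = None
    fluid: Optional[FluidProperties] = None
    reached_top: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if not (self.t.shape == self.H.shape == self.L.shape):
            raise InvalidTrajectoryError("t, H, L must have matching shapes")
        if self.t.ndim != 1:
            raise InvalidTrajectoryError("trajectory arrays must be 1-D")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidTrajectoryError("timestamps must be strictly increasing")
        if np.any(self.H < 0):
            raise InvalidTrajectoryError("heights must be >= 0")

    def __len__(self) -> int:
        return len(self.t)

    def time_at_height(self, H_target: float) -> float:
        """Interpolated time (s) at which the rising front first reaches
        ``H_target`` mm, using monotone (PCHIP) interpolation of t(H) on the
        strictly rising part of the trajectory."""
        H, t = self.H, self.t
        # strictly increasing prefix (drop the saturated plateau)
        keep = np.concatenate(([True], np.diff(H) > 0))
        upto = np.argmin(keep) if not keep.all() else len(H)
        H_rise, t_rise = H[:upto], t[:upto]
        if len(H_rise) < 2:
            raise InvalidTrajectoryError("trajectory has no rising segment")
        if not (H_rise[0] <= H_target <= H_rise[-1]):
            raise UnreachableHeightError(
                f"H_target={H_target} outside sampled rise range "
                f"[{H_rise[0]}, {H_rise[-1]}] mm"
            )
        return float(PchipInterpolator(H_rise, t_rise)(H_target))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "strip_id": self.strip_id,
                "capillary_id": self.capillary_id,
                "time_s": self.t,
                "height_mm": self.H,
                "length_mm": self.L,
            }
        )


# --------------------------------------------------------------------------
# model operations
# --------------------------------------------------------------------------


def capillary_pressure(fluid: FluidProperties, geom: CapillaryGeometry) -> float:
    """Laplace driving pressure P0 = (1/a + 1/b) * gamma*cos(theta), in Pa.

    For a circular bore of radius r this is the familiar 2*gamma*cos(theta)/r.
    """
    return (1.0 / geom.a + 1.0 / geom.b) * fluid.gamma_cos_theta


def hydraulic_diameter(geom: CapillaryGeometry) -> float:
    """Hydraulic diameter 4*area/perimeter of the bore, in m."""
    return geom.dh


def _k(fluid: FluidProperties, geom: CapillaryGeometry) -> float:
    """Mobility k = dh^2 / (32 mu), m^2/(Pa s); v = k * dP / length."""
    return geom.dh**2 / (32.0 * fluid.mu)


def equilibrium_height(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    settings: Optional[ModelSettings] = None,
    device: Optional[DeviceConfig] = None,
) -> float:
    """Equilibrium rise height H_eq = P0 / (rho g), in mm.

    The ``device`` argument is accepted for interface symmetry but has no
    effect: the equilibrium balances Laplace pressure against the
    hydrostatic head only, so it is independent of loop count and loop
    length.  That loop-invariance is the physical basis for calibrating
    surface parameters on straight strips and reusing them on looped ones.
    """
    settings = settings or _DEFAULT_SETTINGS
    p0 = capillary_pressure(fluid, geom)
    return units.m_to_mm(p0 / (fluid.rho * settings.g))


def estimate_gamma_cos_theta(
    H_eq_obs: float,
    rho: float,
    geom: CapillaryGeometry,
    settings: Optional[ModelSettings] = None,
) -> float:
    """Invert an observed equilibrium height (mm) for gamma*cos(theta), N/m.

    ``rho`` in kg/m^3.  Round-trips with :func:`equilibrium_height` to
    machine precision.  Only the product gamma*cos(theta) is identifiable
    from a single equilibrium height; no attempt is made to split it.
    """
    settings = settings or _DEFAULT_SETTINGS
    if not H_eq_obs > 0:
        raise InvalidObservationError(
            f"observed equilibrium height must be > 0 mm, got {H_eq_obs}"
        )
    if not rho > 0:
        raise InvalidFluidError(f"rho must be > 0, got {rho}")
    h_m = units.mm_to_m(H_eq_obs)
    return rho * settings.g * h_m / (1.0 / geom.a + 1.0 / geom.b)


def instantaneous_velocity(
    H,
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: Optional[DeviceConfig] = None,
    settings: Optional[ModelSettings] = None,
):
    """Quasi-steady rise velocity dH/dt at height(s) ``H`` (mm), in mm/s.

    v = [dh^2/(32 mu)] * (P0 - rho g H) / (H + L_loop); positive below the
    equilibrium height, zero at it, negative above.  ``device=None`` means a
    straight strip (L_loop = 0), for which H = 0 is singular.
    """
    settings = settings or _DEFAULT_SETTINGS
    H_arr = np.asarray(H, dtype=float)
    scalar = H_arr.ndim == 0
    H_arr = np.atleast_1d(H_arr)
    if np.any(H_arr < 0):
        raise InvalidObservationError("heights must be >= 0 mm")
    loop_mm = device.loop_length if device is not None else 0.0
    if loop_mm == 0.0 and np.any(H_arr == 0.0):
        raise SingularInputError(
            "velocity is unbounded at H = 0 on a straight strip"
        )
    h_m = units.mm_to_m(H_arr)
    p0 = capillary_pressure(fluid, geom)
    v = _k(fluid, geom) * (p0 - fluid.rho * settings.g * h_m) / (
        h_m + units.mm_to_m(loop_mm)
    )
    v_mm = units.m_to_mm(v)
    return float(v_mm[0]) if scalar else v_mm


def _front_to_HL(ell_mm: np.ndarray, device: DeviceConfig):
    """Map wetted front position (mm along the strip) to (H, L) in mm.

    Before the loop entry the path is vertical (H = position); inside the
    loop the meniscus elevation is held at the entry height (the loop
    diameter is small compared with the equilibrium height); past the loop
    H = position - loop_length.
    """
    e = device.loop_entry_height
    lp = device.loop_length
    if lp == 0.0:
        return ell_mm.copy(), ell_mm.copy()
    H = np.where(
        ell_mm <= e, ell_mm, np.where(ell_mm < e + lp, e, ell_mm - lp)
    )
    return H, ell_mm.copy()


def integrate_rise(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: DeviceConfig,
    settings: Optional[ModelSettings] = None,
    t_grid: Sequence[float] = (),
) -> Trajectory:
    """Integrate the noiseless rise H(t) over the sampling times ``t_grid`` (s).

    Adaptive (LSODA) integration from H0 at t = 0, clamped once H reaches
    (1 - eps_eq) * H_eq or the device's vertical extent, whichever is lower;
    hitting the extent sets ``reached_top``.  L(t) is reported alongside:
    L = H + loop_length once the front is past the loop entry, L = H before.
    """
    settings = settings or _DEFAULT_SETTINGS
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise InvalidScheduleError("t_grid must be a non-empty 1-D sequence")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InvalidScheduleError("t_grid must be strictly increasing")
    if t[0] < 0:
        raise InvalidScheduleError("t_grid must start at or after 0 s")

    p0 = capillary_pressure(fluid, geom)
    rho_g = fluid.rho * settings.g
    h_eq_m = p0 / rho_g
    h0_m = units.mm_to_m(settings.H0)
    if h0_m >= h_eq_m:
        raise UnreachableHeightError(
            f"H0={settings.H0} mm is at or above equilibrium "
            f"({units.m_to_mm(h_eq_m):.3f} mm)"
        )
    k = _k(fluid, geom)
    loop_m = units.mm_to_m(device.loop_length)
    extent_m = units.mm_to_m(device.vertical_extent)
    h_stop = min((1.0 - settings.eps_eq) * h_eq_m, extent_m)

    def rhs(_t, y):
        return [k * (p0 - rho_g * y[0]) / (y[0] + loop_m)]

    def stop_event(_t, y):
        return y[0] - h_stop

    stop_event.terminal = True
    stop_event.direction = 1.0

    if t[-1] == 0.0:
        H_m = np.array([h0_m])
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(t[-1])),
            [h0_m],
            method="LSODA",
            t_eval=t,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            events=stop_event,
            dense_output=False,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust here
            raise RuntimeError(f"rise integration failed: {sol.message}")
        ys = np.asarray(sol.y)
        H_m = ys[0] if ys.size else np.empty(0)
        if len(H_m) < len(t):
            # terminated at the clamp; hold the plateau value
            H_m = np.concatenate([H_m, np.full(len(t) - len(H_m), h_stop)])
        H_m = np.minimum(H_m, h_stop)

    reached_top = extent_m < (1.0 - settings.eps_eq) * h_eq_m and bool(
        H_m[-1] >= extent_m * (1.0 - 1e-12)
    )
    H_mm = units.m_to_mm(H_m)
    if device.loop_length > 0:
        passed = H_mm >= device.loop_entry_height
        L_mm = np.where(passed, H_mm + device.loop_length, H_mm)
    else:
        L_mm = H_mm.copy()
    return Trajectory(
        strip_id=device.name,
        capillary_id=0,
        t=t,
        H=H_mm,
        L=L_mm,
        device=device,
        fluid=fluid,
        reached_top=reached_top,
    )


def time_to_height(
    H_target: float,
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: Optional[DeviceConfig] = None,
    settings: Optional[ModelSettings] = None,
) -> float:
    """Time (s) for the front to rise from H0 to ``H_target`` mm, by quadrature.

    Separates the velocity law into dt = (H + L_loop) / (k (P0 - rho g H)) dH
    and integrates it with adaptive quadrature -- an independent companion to
    :func:`integrate_rise` used for cross-validation and design sweeps.
    """
    settings = settings or _DEFAULT_SETTINGS
    p0 = capillary_pressure(fluid, geom)
    rho_g = fluid.rho * settings.g
    h_eq_mm = units.m_to_mm(p0 / rho_g)
    if H_target >= h_eq_mm:
        raise UnreachableHeightError(
            f"H_target={H_target} mm is at or above equilibrium ({h_eq_mm:.3f} mm)"
        )
    if device is not None and H_target > device.vertical_extent:
        raise UnreachableHeightError(
            f"H_target={H_target} mm exceeds the device's vertical extent"
        )
    if H_target < settings.H0:
        raise InvalidObservationError(
            f"H_target={H_target} mm lies below the starting height H0={settings.H0} mm"
        )
    if H_target == settings.H0:
        return 0.0
    k = _k(fluid, geom)
    loop_m = units.mm_to_m(device.loop_length) if device is not None else 0.0

    def integrand(h_m):
        return (h_m + loop_m) / (k * (p0 - rho_g * h_m))

    t, _ = quad(
        integrand,
        units.mm_to_m(settings.H0),
        units.mm_to_m(H_target),
        epsabs=1e-12,
        epsrel=1e-10,
        limit=200,
    )
    return t


def loop_residence_time(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    device: DeviceConfig,
    settings: Optional[ModelSettings] = None,
) -> float:
    """Time (s) the advancing front spends traversing the loop region.

    Uses the front-propagation form d(ell)/dt = k (P0 - rho g z) / ell with
    the meniscus elevation z held at the loop entry height while the front
    is inside the loop (loop diameters of 9-14 mm are small against the
    equilibrium height), which integrates in closed form to

        t = (ell2^2 - ell1^2) / (2 k (P0 - rho g z_loop)),

    ell1 = entry height, ell2 = entry height + loop_length.  Longer loops
    and higher viscosities strictly increase the residence time, which is
    what sets the stimulation duration of a looped strip.
    """
    settings = settings or _DEFAULT_SETTINGS
    if device.loop_length == 0.0:
        return 0.0
    p0 = capillary_pressure(fluid, geom)
    rho_g = fluid.rho * settings.g
    z_m = units.mm_to_m(device.loop_entry_height)
    if rho_g * z_m >= p0:
        raise StalledFrontError(
            "loop entry height is at or above the equilibrium height; "
            "the front never traverses the loop"
        )
    l1 = z_m
    l2 = z_m + units.mm_to_m(device.loop_length)
    k = _k(fluid, geom)
    return (l2**2 - l1**2) / (2.0 * k * (p0 - rho_g * z_m))
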