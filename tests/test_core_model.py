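"""Core pressure-balance model: pressures, equilibria, velocities, rise times."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import ellipe

import capflow as cf
from capflow.errors import (
    InvalidFluidError,
    InvalidGeometryError,
    InvalidObservationError,
    InvalidScheduleError,
    SingularInputError,
    StalledFrontError,
    UnreachableHeightError,
)

from conftest import rise_time_closed_form


class TestGeometry:
    def test_circle_hydraulic_diameter_exact(self):
        g = cf.CapillaryGeometry(a=100e-6, b=100e-6)
        assert g.dh == 200e-6

    @pytest.mark.parametrize("a,b", [(100e-6, 50e-6), (150e-6, 30e-6), (1e-3, 0.9e-3)])
    def test_ellipse_dh_matches_exact_perimeter_integral(self, a, b):
        # oracle: exact perimeter 4 a E(e^2) via the complete elliptic integral
        p_exact = 4.0 * a * ellipe(1.0 - (b / a) ** 2)
        dh_exact = 4.0 * math.pi * a * b / p_exact
        g = cf.CapillaryGeometry(a=a, b=b)
        assert g.dh == pytest.approx(dh_exact, rel=1e-3)

    def test_degenerate_minor_axis_shrinks_dh_monotonically(self):
        a = 100e-6
        dhs = [cf.CapillaryGeometry(a=a, b=b).dh for b in (80e-6, 40e-6, 10e-6, 1e-6)]
        assert all(x > y for x, y in zip(dhs, dhs[1:]))
        assert dhs[-1] < 4e-6

    def test_invalid_axes_rejected(self):
        with pytest.raises(InvalidGeometryError):
            cf.CapillaryGeometry(a=50e-6, b=100e-6)
        with pytest.raises(InvalidGeometryError):
            cf.CapillaryGeometry(a=-1e-6, b=-1e-6)


class TestFluid:
    def test_gamma_theta_reduce_to_product(self):
        f = cf.FluidProperties("x", rho=1000, mu=1e-3, gamma=0.072, theta=60.0)
        assert f.gamma_cos_theta == pytest.approx(0.036, rel=1e-12)

    def test_inconsistent_gamma_theta_product_rejected(self):
        with pytest.raises(InvalidFluidError):
            cf.FluidProperties(
                "x", rho=1000, mu=1e-3, gamma_cos_theta=0.04, gamma=0.072, theta=60.0
            )

    def test_lab_unit_conversion(self):
        f = cf.FluidProperties.from_lab_units("w", 0.998, 1.04, gamma_cos_theta=0.037)
        assert f.rho == pytest.approx(998.0)
        assert f.mu == pytest.approx(1.04e-3)
        assert f.mu_cp == pytest.approx(1.04)


class TestPressureAndEquilibrium:
    def test_zero_wetting_gives_zero_pressure_and_height(self, geom):
        f = cf.FluidProperties("dry", rho=1000, mu=1e-3, gamma_cos_theta=0.0)
        assert cf.capillary_pressure(f, geom) == 0.0
        assert cf.equilibrium_height(f, geom) == 0.0

    def test_circular_bore_reproduces_laplace_form(self):
        # a = b = r must give 2*gamma*cos(theta)/r
        r = 100e-6
        f = cf.FluidProperties("w", rho=998, mu=1e-3, gamma_cos_theta=0.03735)
        p0 = cf.capillary_pressure(f, cf.CapillaryGeometry(a=r, b=r))
        assert p0 == pytest.approx(2 * 0.03735 / r, rel=1e-14)
        assert p0 == pytest.approx(747.0, rel=1e-6)

    def test_water_equilibrium_matches_calibration(self, water, geom):
        assert cf.equilibrium_height(water, geom) == pytest.approx(76.3, rel=1e-12)

    def test_equilibrium_halves_when_density_doubles(self, water, geom):
        heavy = dataclasses.replace(water, rho=2 * water.rho)
        assert cf.equilibrium_height(heavy, geom) == pytest.approx(
            cf.equilibrium_height(water, geom) / 2, rel=1e-12
        )

    def test_gamma_estimate_round_trips_with_equilibrium(self, geom):
        for h in (5.0, 40.0, 76.3, 120.0):
            gct = cf.estimate_gamma_cos_theta(h, 998.0, geom)
            f = cf.FluidProperties("w", rho=998.0, mu=1e-3, gamma_cos_theta=gct)
            assert cf.equilibrium_height(f, geom) == pytest.approx(h, rel=1e-13)

    def test_gamma_estimate_printed_values(self, geom):
        assert cf.estimate_gamma_cos_theta(76.3, 998.0, geom) == pytest.approx(
            0.03735, abs=5e-6
        )
        # whole blood: 72.7 mm at rho = 1.055 g/mL
        assert cf.estimate_gamma_cos_theta(72.7, 1055.0, geom) == pytest.approx(
            0.0376, abs=5e-5
        )

    def test_gamma_estimate_vanishes_in_small_height_limit(self, geom):
        assert cf.estimate_gamma_cos_theta(1e-9, 998.0, geom) < 1e-12

    def test_gamma_estimate_rejects_nonpositive_heights(self, geom):
        with pytest.raises(InvalidObservationError):
            cf.estimate_gamma_cos_theta(0.0, 998.0, geom)
        with pytest.raises(InvalidObservationError):
            cf.estimate_gamma_cos_theta(-5.0, 998.0, geom)


class TestVelocity:
    def test_fixture_values(self, water, geom, straight, loop1):
        assert cf.instantaneous_velocity(53.1, water, geom, straight) == pytest.approx(
            5.14, rel=2e-3
        )
        assert cf.instantaneous_velocity(53.1, water, geom, loop1) == pytest.approx(
            2.84, rel=2e-3
        )

    def test_zero_at_equilibrium_and_sign_change(self, water, geom, straight):
        h_eq = cf.equilibrium_height(water, geom)
        assert cf.instantaneous_velocity(h_eq, water, geom, straight) == pytest.approx(
            0.0, abs=1e-12
        )
        assert cf.instantaneous_velocity(0.9 * h_eq, water, geom, straight) > 0
        assert cf.instantaneous_velocity(1.1 * h_eq, water, geom, straight) < 0

    def test_strictly_decreasing_in_height_below_equilibrium(self, water, geom, loop1):
        H = np.linspace(1.0, 76.0, 200)
        v = cf.instantaneous_velocity(H, water, geom, loop1)
        assert np.all(np.diff(v) < 0)

    def test_singular_at_zero_height_straight(self, water, geom, straight):
        with pytest.raises(SingularInputError):
            cf.instantaneous_velocity(0.0, water, geom, straight)

    def test_homogeneous_degree_minus_one_in_viscosity(self, water, geom, loop1):
        H = np.array([10.0, 30.0, 60.0])
        v1 = cf.instantaneous_velocity(H, water, geom, loop1)
        v2 = cf.instantaneous_velocity(H, water.with_mu(2 * water.mu), geom, loop1)
        np.testing.assert_allclose(v2, v1 / 2, rtol=1e-13)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    rho=st.floats(900, 1200),
    mu_cp=st.floats(0.8, 10),
    gct=st.floats(0.02, 0.06),
    d_um=st.floats(120, 300),
    loop_mm=st.floats(0, 80),
    frac=st.floats(0.05, 0.95),
)
def test_equilibrium_is_loop_invariant_and_velocity_sign_follows_balance(
    rho, mu_cp, gct, d_um, loop_mm, frac
):
    """H_eq does not depend on the loop; sign(v) = sign(H_eq - H)."""
    geom = cf.CapillaryGeometry.circle(d_um * 1e-6)
    fluid = cf.FluidProperties("f", rho=rho, mu=mu_cp * 1e-3, gamma_cos_theta=gct)
    dev = (
        cf.DeviceConfig("d", strip_length=500.0, n_loops=1, loop_length=loop_mm,
                        loop_entry_height=5.0, loop_diameter=5.0)
        if loop_mm > 0
        else cf.DeviceConfig.straight(500.0)
    )
    h_eq = cf.equilibrium_height(fluid, geom)
    assert cf.equilibrium_height(fluid, geom, device=dev) == h_eq
    h = frac * h_eq
    if h > 0:
        assert cf.instantaneous_velocity(h, fluid, geom, dev) > 0
    assert cf.instantaneous_velocity(1.5 * h_eq, fluid, geom, dev) < 0


class TestRiseIntegration:
    def test_initial_condition(self, water, geom, straight):
        traj = cf.integrate_rise(water, geom, straight, None, [0.0, 1.0])
        assert traj.H[0] == pytest.approx(0.1, abs=1e-12)

    def test_monotone_and_bounded_by_equilibrium(self, water, geom, loop1):
        t = np.linspace(0.0, 120.0, 500)
        traj = cf.integrate_rise(water, geom, loop1, None, t)
        assert np.all(np.diff(traj.H) >= 0)
        assert traj.H[-1] <= cf.equilibrium_height(water, geom) + 1e-9
        assert traj.H[-1] == pytest.approx(76.3, abs=0.1)

    @pytest.mark.parametrize("loop_mm", [0.0, 43.0, 58.0])
    def test_crossing_time_matches_closed_form(self, water, geom, devices, loop_mm):
        dev = {0.0: "straight-100", 43.0: "loop1-150", 58.0: "loop2-160"}[loop_mm]
        device = devices[dev]
        t_oracle = rise_time_closed_form(
            53.1, water.rho, water.mu, water.gamma_cos_theta, 200e-6, loop_mm
        )
        t_grid = np.linspace(0.0, 1.2 * t_oracle, 2001)
        traj = cf.integrate_rise(water, geom, device, None, t_grid)
        assert traj.time_at_height(53.1) == pytest.approx(t_oracle, rel=1e-5)
        assert cf.time_to_height(53.1, water, geom, device) == pytest.approx(
            t_oracle, rel=1e-8
        )

    def test_length_accounting(self, water, geom, loop1, straight):
        t = np.linspace(0.5, 60.0, 120)
        trajL = cf.integrate_rise(water, geom, loop1, None, t)
        past = trajL.H >= loop1.loop_entry_height
        np.testing.assert_allclose(trajL.L[past], trajL.H[past] + 43.0)
        np.testing.assert_allclose(trajL.L[~past], trajL.H[~past])
        trajS = cf.integrate_rise(water, geom, straight, None, t)
        np.testing.assert_allclose(trajS.L, trajS.H)

    def test_saturates_at_vertical_extent(self, water, geom):
        # a shallow device whose extent is below the equilibrium height
        dev = cf.DeviceConfig("short", strip_length=50.0, n_loops=0, loop_length=0.0)
        traj = cf.integrate_rise(water, geom, dev, None, np.linspace(0, 60, 200))
        assert traj.reached_top
        assert traj.H[-1] == pytest.approx(50.0, rel=1e-9)

    def test_rejects_bad_schedules(self, water, geom, straight):
        with pytest.raises(InvalidScheduleError):
            cf.integrate_rise(water, geom, straight, None, [0.0, 1.0, 1.0])
        with pytest.raises(InvalidScheduleError):
            cf.integrate_rise(water, geom, straight, None, [-1.0, 1.0])


class TestTimeToHeight:
    def test_zero_at_start_height(self, water, geom, straight):
        assert cf.time_to_height(0.1, water, geom, straight) == 0.0

    def test_monotone_in_loop_length(self, water, geom, straight, loop1, loop2):
        ts = [cf.time_to_height(53.1, water, geom, d) for d in (straight, loop1, loop2)]
        assert ts[0] < ts[1] < ts[2]

    def test_unreachable_above_equilibrium(self, water, geom, straight):
        with pytest.raises(UnreachableHeightError):
            cf.time_to_height(80.0, water, geom, straight)


class TestLoopResidence:
    def test_closed_form_against_quadrature(self, water, geom, loop1):
        dev = dataclasses.replace(loop1, loop_entry_height=20.0)
        t = cf.loop_residence_time(water, geom, dev)
        # oracle: numeric quadrature of dt = ell / (k (P0 - rho g z)) d(ell)
        p0 = cf.capillary_pressure(water, geom)
        k = geom.dh**2 / (32 * water.mu)
        dp = p0 - water.rho * 9.81 * 0.020
        t_quad, _ = quad(lambda l: l / (k * dp), 0.020, 0.020 + 0.043)
        assert t == pytest.approx(t_quad, rel=1e-12)
        assert t == pytest.approx(2.69, rel=2e-3)

    def test_zero_loop_zero_time(self, water, geom, straight):
        assert cf.loop_residence_time(water, geom, straight) == 0.0

    def test_increases_with_loop_length_and_viscosity(self, water, geom, loop1, loop2):
        d1 = dataclasses.replace(loop1, loop_entry_height=20.0)
        d2 = dataclasses.replace(loop2, loop_entry_height=20.0)
        assert cf.loop_residence_time(water, geom, d2) > cf.loop_residence_time(
            water, geom, d1
        )
        thick = water.with_mu(2 * water.mu)
        assert cf.loop_residence_time(thick, geom, d1) == pytest.approx(
            2 * cf.loop_residence_time(water, geom, d1), rel=1e-12
        )

    def test_stalled_when_entry_at_equilibrium(self, water, geom):
        dev = cf.DeviceConfig(
            "high", strip_length=300.0, n_loops=1, loop_length=43.0,
            loop_entry_height=80.0, loop_diameter=9.0,
        )
        with pytest.raises(StalledFrontError):
            cf.loop_residence_time(water, geom, dev)
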