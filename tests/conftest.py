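import math

import numpy as np
import pytest

import capflow as cf

WATER_EQ_MM = 76.3  # straight-strip equilibrium used for surface calibration


@pytest.fixture(scope="session")
def geom():
    """Circular 200 um bore."""
    return cf.CapillaryGeometry.circle(200e-6)


@pytest.fixture(scope="session")
def water(geom):
    """Water with gamma*cos(theta) calibrated from the straight-strip
    equilibrium height (76.3 mm)."""
    gct = cf.estimate_gamma_cos_theta(WATER_EQ_MM, 998.0, geom)
    return cf.FluidProperties.from_lab_units("water", 0.998, 1.04, gamma_cos_theta=gct)


@pytest.fixture(scope="session")
def devices():
    return cf.device_presets()


@pytest.fixture(scope="session")
def straight(devices):
    return devices["straight-100"]


@pytest.fixture(scope="session")
def loop1(devices):
    return devices["loop1-150"]


@pytest.fixture(scope="session")
def loop2(devices):
    return devices["loop2-160"]


def rise_time_closed_form(H_target_mm, rho, mu_pa_s, gct, bore_d_m, loop_mm=0.0,
                          H0_mm=0.1, g=9.81):
    """Independent closed-form oracle for the rise time.

    dt = (H + L) / (k (P0 - rho g H)) dH integrates to
    t = [ (H_eq + L) ln((H_eq - H0)/(H_eq - Ht)) - (Ht - H0) ] / (k rho g).
    """
    r = bore_d_m / 2.0
    p0 = 2.0 * gct / r
    k = bore_d_m**2 / (32.0 * mu_pa_s)
    h_eq = p0 / (rho * g)
    h0, ht, L = H0_mm * 1e-3, H_target_mm * 1e-3, loop_mm * 1e-3
    return ((h_eq + L) * math.log((h_eq - h0) / (h_eq - ht)) - (ht - h0)) / (k * rho * g)
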