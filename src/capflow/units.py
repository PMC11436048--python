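"""Unit conversions.

SI everywhere inside the model; interfaces speak the lab's units
(mm, s, cP, g/mL, um). All conversions live here so no factor of 1000 is
ever typed twice.
"""

MM_PER_M = 1e3
M_PER_MM = 1e-3
M_PER_UM = 1e-6

PA_S_PER_CP = 1e-3
CP_PER_PA_S = 1e3

KG_M3_PER_G_ML = 1e3
G_ML_PER_KG_M3 = 1e-3

#: standard gravitational acceleration, m/s^2
STANDARD_GRAVITY = 9.81


def mm_to_m(x):
    return x * M_PER_MM


def m_to_mm(x):
    return x * MM_PER_M


def cp_to_pa_s(x):
    return x * PA_S_PER_CP


def pa_s_to_cp(x):
    return x * CP_PER_PA_S


def g_ml_to_kg_m3(x):
    return x * KG_M3_PER_G_ML
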