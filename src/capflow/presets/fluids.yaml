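# Fluid presets. rho in g/mL, mu in cP, gamma_cos_theta in N/m.
#
# water/PRP/WB densities and viscosities are literature values for those
# fluid classes; their gamma_cos_theta values are calibrated from straight-
# strip equilibrium heights (76.3 / 75.4 / 72.7 mm) with a circular 200 um
# bore and g = 9.81 m/s^2.  HBS/PPP/RBC properties are NOT literature-fixed
# here; they are documented assumptions (source: assumed) chosen to sit in
# the plausible range for those fluid classes.
water:
  rho_g_per_ml: 0.998
  mu_cp: 1.04
  gamma_cos_theta: 0.03735030
  source: printed
PRP:
  rho_g_per_ml: 1.025
  mu_cp: 1.7
  gamma_cos_theta: 0.03790829
  source: printed
WB:
  rho_g_per_ml: 1.055
  mu_cp: 6.0
  gamma_cos_theta: 0.03762061
  source: printed
HBS:
  rho_g_per_ml: 1.007
  mu_cp: 1.05
  gamma_cos_theta: 0.0380
  source: assumed
PPP:
  rho_g_per_ml: 1.024
  mu_cp: 1.3
  gamma_cos_theta: 0.0379
  source: assumed
RBC:
  rho_g_per_ml: 1.093
  mu_cp: 4.0
  gamma_cos_theta: 0.0376
  source: assumed
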