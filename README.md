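# capflow

Pressure-balance modelling and analysis of capillary rise in straight and
looped microcapillary film (MCF) test strips.

Low-cost "dip-and-test" haemostasis assays draw a blood sample up a bundle
of ~200 µm polymer capillaries by capillary action alone; the height and
velocity of the rising column report on the sample's viscosity, and hence
on clotting triggered by stimuli dried inside the strip. Coiling an extra
*loop* of capillary near the inlet adds frictional path length, slowing the
rise and lengthening the time the sample spends exposed to the stimulus —
without changing the equilibrium height. `capflow` provides the quantitative
toolkit for designing and analysing such devices: the flow model, the
trajectory-analysis chain used on time-lapse height data, replicate group
statistics, and a synthetic-data generator so that every stage is testable
end to end.

## Model

The quasi-steady pressure balance for a vertical elliptical capillary with
semi-axes *a*, *b* and hydraulic diameter *d*<sub>h</sub> equates the Laplace
driving pressure to the hydrostatic head plus Poiseuille friction along the
wetted length *L*(*t*):

```
dH/dt = (d_h² / 32 µ) · [ (1/a + 1/b) γ cosθ − ρ g H(t) ] / L(t)
```

* straight strip: `L(t) = H(t)`
* strip with a looped region of extra path length `L_loop`:
  `L(t) = H(t) + L_loop`

with γ cosθ the product of surface tension and contact-angle cosine (the
only surface quantity identifiable from an equilibrium height), ρ the
density, µ the dynamic viscosity and g gravity. Consequences the package
exposes as operations and verifies as properties:

* **Equilibrium** `H_eq = P0/(ρg)` with `P0 = (1/a + 1/b) γcosθ` is
  *independent of the loop* — so γcosθ calibrated on straight strips
  transfers to looped ones (`equilibrium_height`, `estimate_gamma_cos_theta`).
* **Affine law**: on straight strips `v = (k P0)·(1/H) − k ρ g` with
  `k = d_h²/(32 µ)`, i.e. velocity is linear in the reciprocal height 1/H.
* **Ordering**: at any height below equilibrium, straight > 1 loop > 2 loops
  in velocity; residence time in the loop grows with loop length and µ
  (`instantaneous_velocity`, `loop_residence_time`).
* **Rise times** by stiff-safe ODE integration (`integrate_rise`) and,
  independently, by adaptive quadrature of
  `dt = (H + L_loop) dH / (k (P0 − ρgH))` (`time_to_height`).

The analysis chain (`finite_difference_velocity`,
`reciprocal_window_filter`, `predict_velocity_curve`,
`estimate_surface_params`, `fit_viscosity`, `one_way_anova`, `tukey_hsd`)
mirrors how time-lapse data are reduced: finite-difference velocities from
sequential heights, profiling against 1/H inside the 0.0125–0.06 mm⁻¹
window (heights 16.7–80 mm), model overlay, and loop-effect statistics.

## Worked example

Simulate a full water/PRP/whole-blood × straight/1-loop/2-loop experiment
(10 replicate capillaries each, 1 s sampling for 10 min, 0.5 mm height
noise) and analyse it:

```bash
cat > config.yaml <<'YAML'
seed: 7
fluids: [water, PRP, WB]
devices: [straight-100, loop1-150, loop2-160]
schedule: {t_start: 1.0, t_end: 600.0, interval: 1.0}
noise: {sigma_H: 0.5, sigma_t: 0.05, replicate_cv: 0.0}
n_capillaries: 10
analysis: {window_inv_H: [0.0125, 0.06], comparison_timepoint: 30.0}
YAML
capflow simulate --config config.yaml --out out
capflow analyze out/dataset.csv --config config.yaml --out out
capflow report out/analysis.json
```

prints (abridged):

```
analysis window: 1/H in [0.0125, 0.06] 1/mm (heights 16.7-80.0 mm)

Equilibrium heights and viscosity fits
             strip  n H_eq obs (mm) H_eq model (mm) mu fit (cP)
  PRP@straight-100 10  75.3 +/- 0.2            75.3        1.70
   WB@straight-100 10  72.7 +/- 0.2            72.7        5.99
water@straight-100 10  76.3 +/- 0.4            76.3        1.06
...

Surface-parameter fits (straight strips)
fluid gamma*cos(theta) (N/m) +/- (N/m) from H_eq (mm)  n
  PRP                0.03787   0.00010           75.3 10
   WB                0.03762   0.00012           72.7 10
water                0.03735   0.00018           76.3 10

Loop effect on heights at t = 30.0 s (one-way ANOVA + Tukey HSD)
  water: F(2,27) = 105.2, p = 1.8e-13
    loop1-150 vs straight-100: diff = -1.72 mm, p_adj = 2.1e-08
    ...
```

Reading this: the recovered equilibrium heights reproduce the calibration
values of the presets (water 76.3 mm, PRP 75.4 mm, WB 72.7 mm) on straight
*and* looped strips — the loop does not change the capillary force — while
the fitted viscosities recover the generating 1.04 / 1.7 / 6 cP to within
the noise, and the 30 s heights separate strongly by loop count (the slower
flow through added loop friction). `capflow report --plot out/plots` also
draws the v vs 1/H profiles with model overlays.

The same machinery is available as a library:

```python
import capflow as cf

geom = cf.CapillaryGeometry.circle(200e-6)          # 200 um bore
gct = cf.estimate_gamma_cos_theta(76.3, 998.0, geom)  # from straight-strip H_eq
water = cf.FluidProperties.from_lab_units("water", 0.998, 1.04,
                                          gamma_cos_theta=gct)
loop1 = cf.device_presets()["loop1-150"]
cf.equilibrium_height(water, geom, device=loop1)     # 76.3 mm (loop-invariant)
cf.instantaneous_velocity(53.1, water, geom, loop1)  # 2.84 mm/s
cf.time_to_height(53.1, water, geom, loop1)          # 7.55 s
```

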