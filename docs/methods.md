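# Methods

## The pressure-balance model

`capflow` models capillary rise in a vertical microcapillary as a
quasi-steady balance of three pressures: the Laplace (wetting) pressure
`P0 = (1/a + 1/b) γcosθ` drawing liquid into an elliptical bore of
semi-axes *a* ≥ *b*, the hydrostatic head `ρ g H` of the risen column, and
Poiseuille-type viscous friction along the wetted length. The net
superficial velocity is

    dH/dt = k (P0 − ρ g H) / L,     k = d_h² / (32 µ),

with hydraulic diameter `d_h = 4·area/perimeter` and wetted length
`L = H` (straight strip) or `L = H + L_loop` (strip with a looped region of
extra path length `L_loop` near the inlet). Assumptions inherited from this
form: fully developed laminar flow, quasi-steady (no inertia), a static
contact angle, and no secondary-flow (Dean/centrifugal) losses inside the
loop. These are adequate for early-to-mid rise; real data deviate toward
lower velocities as the column nears equilibrium, so parameter fits are
restricted to the reciprocal-height window below.

Interpreting *a* and *b* as **semi**-axes is deliberate: the circular limit
a = b = r then reproduces the Laplace pressure `2 γcosθ / r`. Any other
convention breaks that limit. For non-circular bores the ellipse perimeter
uses Ramanujan's second approximation (relative error ≲ 1e-9 over the
relevant eccentricities, verified against the exact elliptic-integral
perimeter); a measured `d_h` may also be supplied directly. The default
geometry is a circular 200 µm bore.

Only the product γcosθ is identifiable from an equilibrium height — the
package therefore estimates and carries the product, never a separate
surface tension and contact angle (separate γ, θ are accepted as inputs and
reduced immediately). Calibration inverts `H_eq = P0/(ρg)` on straight
strips; because the equilibrium is loop-invariant, the calibrated value
transfers to looped devices unchanged. This loop-invariance is asserted
exactly in the tests rather than assumed silently.

## Numerical choices

- **Integration** (`integrate_rise`): the velocity law is singular at
  H = 0 for straight strips, so trajectories start at `H0 = 0.1 mm`
  (configurable). LSODA with rtol 1e-8 / atol 1e-12 (SI), with a terminal
  event at `(1 − eps_eq)·H_eq` (eps_eq = 1e-6) or at the device's vertical
  extent; past the event the height is held at the clamp value, and hitting
  the extent flags the trajectory `reached_top`. The near-equilibrium
  approach is exponential, so the clamp avoids integrating an asymptote.
- **Rise times** (`time_to_height`): independent adaptive quadrature of
  `dt = (H + L_loop) dH / (k (P0 − ρgH))`; agrees with the ODE route to
  better than 1e-4 relative (tested over random parameter draws), and both
  agree with the closed-form antiderivative used as a third oracle in the
  tests.
- **Loop residence time**: inside the loop the meniscus elevation is
  approximated as constant at the loop entry height (loop diameters of
  9–14 mm are small against ~76 mm equilibria), giving the closed form
  `t = (ℓ₂² − ℓ₁²) / (2 k (P0 − ρ g z_loop))` for the front position ℓ.
  The same piecewise-elevation front model drives the stimulated-viscosity
  generator; the plain trajectory integrator instead applies the
  `H + L_loop` law throughout, which is the model form used for all
  post-loop (measurement-zone) analysis.
- **Finite-difference velocities**: each consecutive sample pair yields
  `ΔH/Δt` assigned to the midpoint height and time, which is second-order
  accurate in the sampling interval (verified by a convergence test); Δt
  always comes from actual timestamps, so timestamp jitter does not bias
  velocities.
- **Viscosity fitting**: with ρ and γcosθ known, the model velocity is
  linear in 1/µ; the fit minimises velocity-space residuals by bounded
  scalar search on µ ∈ [0.01, 1000] cP (xatol 1e-8). Residuals are taken in
  v (not 1/H) because the measurement noise lives on heights. Points at or
  above equilibrium carry no viscosity information and are excluded; fewer
  than three usable points is an error, not a guess.
- **Analysis window**: profiling and fits use the reciprocal-height window
  [0.0125, 0.06] mm⁻¹ (heights 16.7–80 mm) by default — the regime where
  velocities are slow enough for finite differences to be reliable and the
  affine law is informative.
- **Group statistics**: the one-way ANOVA decomposition (SSB/SSW, F, p) is
  computed directly; Tukey's HSD uses the standard studentized-range
  routine, cross-checked in the tests against a brute-force double
  quadrature of the studentized-range distribution. Shapiro–Wilk normality
  is computed and reported per group but gates nothing. Significance is
  read at p < 0.05. Zero within-group variance (e.g. noiseless synthetic
  replicates) is reported as degenerate rather than producing an infinite F.

## The synthetic-data generator

`simulate_strip` emulates what the imaging rig produces: per capillary it
(1) optionally perturbs γcosθ by a lognormal multiplier with coefficient of
variation `replicate_cv`, (2) integrates the noiseless model, (3) samples
at nominal times plus Gaussian jitter (SD `sigma_t`), (4) adds Gaussian
height noise (SD `sigma_H`), clamped to [0, vertical_extent]. Defaults:
`sigma_H = 0.5 mm`, `sigma_t = 0.05 s`, `replicate_cv = 0` — the height and
timing scatter are chosen to be of the order of the replicate error bars
seen in this kind of assay, while inter-capillary surface variability is
off by default because its physical origin (bore vs coating variation) is
not separable from published data; it is exposed as an explicit knob.
Streams are counter-based (numpy Philox keyed by
`SeedSequence(seed, spawn_key=(strip, capillary))`), so identical
seed + config reproduce datasets bitwise and changing the replicate count
does not shift other capillaries' streams. With all noise terms zero the
generator output equals the core-model trajectory exactly.

`stimulated_viscosity_trajectory` emulates agonist-triggered clotting with
a purely phenomenological viscosity ramp
`µ(t) = min(µ_max, µ_baseline + ramp_rate·(t − onset))`. This is *not* a
coagulation-kinetics model: it reproduces only the qualitative phenomenology
— higher µ_max gives lower heights, the looped-vs-straight height gap
widens with stimulation strength in the moderate-ramp regime (stimulation
acting while the looped sample is still near the loop), and steep ramps
stall the front inside the looped region, the regime where heavily
stimulated blood cannot pass the loop. Because both straight and looped
flows eventually stall under extreme ramps, the gap-widening is a
moderate-regime property, not a global monotonicity.

What passing the synthetic-data tests does **not** show about real data:
the generator contains no dynamic contact angle, no loop secondary flows,
no sample-to-sample (donor) variability, no image-segmentation artefacts,
and its noise is Gaussian and homoscedastic. Parameter-recovery rates
measured on it are therefore best-case figures for the analysis chain, not
field performance.

## Presets and fluids

Shipped fluid presets carry literature density/viscosity values for water
(0.998 g/mL, 1.04 cP), platelet-rich plasma (1.025, 1.7) and whole blood
(1.055, 6), with γcosθ calibrated from straight-strip equilibrium heights
of 76.3 / 75.4 / 72.7 mm under the default geometry. HBS, platelet-poor
plasma and red-blood-cell presets are **documented assumptions** (flagged
`source: assumed` in `presets/fluids.yaml`): their heights have been
observed in such assays but their bulk properties are not pinned down here.
Device presets: 100 mm straight; 150 mm with a 43 mm single-loop region
(14 mm loop diameter); 160 mm with a 58 mm double-loop region (9 mm
diameter) — the 58 mm is treated as the *total* extra path length of the
double-looped region. The loop entry height (20 mm) is an assumption used
only by residence-time and stall calculations.

## Problem sizes used in tests

The suite exercises the pipeline at sizes chosen to estimate each quantity
well while keeping runs quick: noiseless convergence checks use 0.05–0.2 s
sampling over ≤ 30 s; parameter-recovery statistics use 100 seeded
experiments of 10 capillaries sampled at 0.5 s for 60 s; the loop-effect
significance rate uses 100 seeded runs of 3 fluids × 3 devices × 10
capillaries read out at 30 s; equilibrium readouts use 600 s schedules,
matching a 10-minute endpoint measurement.

## Known limitations

- The model is the simple pressure balance: no dynamic contact angle,
  inertial, or centrifugal/Dean-flow corrections. Real velocities fall
  below the prediction near equilibrium; fits outside the analysis window
  will absorb that misfit into µ.
- Within-loop elevation is approximated as constant; residence times are
  accordingly approximate at the few-percent level for large loop
  diameters.
- Equilibrium estimates from finite schedules are biased low if the
  schedule ends before the column settles (slow, viscous fluids on looped
  strips need several minutes); the default 600 s schedule covers the
  shipped presets.
- The stimulation ramp is phenomenological; none of its parameters map onto
  agonist concentrations except by qualitative ordering.
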