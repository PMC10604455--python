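# Model and methods

`thyrorfa` simulates monopolar radiofrequency (RF) ablation of a benign
thyroid nodule and plans the generator settings — applied power and
treatment duration — that reach a target volume reduction rate (VRR)
without overheating healthy tissue beyond a safety distance.

## Physical model

**Electric problem.** At 480 kHz the RF wavelength vastly exceeds the
anatomy, so the current distribution obeys the quasi-static conduction
equation `div(sigma grad V) = 0`. The active tip is an equipotential
conductor (Dirichlet block; copper at 5.99e7 S/m is effectively
equipotential, and eliminating its interior avoids a 1e8 conductivity
contrast in the matrix), the dispersive ground pad is `V = 0` on the outer
box boundaries except the skin surface, and the insulated shaft
(1e-5 S/m) participates as a very poor conductor. Joule heating is
`Qp = sigma |grad V|^2`.

**Constant-power control.** The problem is linear in `V` at frozen
`sigma(T)`, so one unit-potential solve per conductivity state suffices:
scaling `V` by `sqrt(P_target / P_unit)` delivers the setpoint exactly,
and the tip-to-ground impedance `Z = V^2 / P` is scale-invariant. The unit
solution is reused until the conductivity field has drifted more than 1 %
(configurable; 0 re-solves every step).

**Bioheat.** Temperature follows the Pennes equation
`rho c_p dT/dt - div(k grad T) = Qp + rho_b c_b omega_b (T_b - T) + Q_met`
with body-temperature Dirichlet boundaries on the grounded outer surfaces
and convective exchange (`h = 10 W/m^2/K`, `T_ext = 25 degC`) on the skin.
The external boundary condition set is our reconciliation of two stated
conditions (uniform 37 degC everywhere vs. skin convection): Robin on the
skin face, Dirichlet elsewhere; both are configurable.

**Constitutive laws.** Electrical conductivity rises 1.5 %/K
(`sigma = sigma_ref (1 + 0.015 (T - 37))`, clamped at 1e-6 S/m against
extreme extrapolation), thermal conductivity rises 0.0013 W/m/K per K, and
blood perfusion decays with accumulated damage as `omega_b0 exp(-D)`.
Blood density and specific heat are not part of the reference property
table; we adopt the standard literature values 1050 kg/m^3 and
3617 J/kg/K (configurable). Relative permittivity is stored for
completeness but unused by the conduction solve.

**Damage.** First-order Arrhenius kinetics
`D(t) = A int exp(-dE/(R T)) dtau` (T in kelvin), damaged fraction
`theta = 1 - exp(-D)`. The ablated ("removed") nodule volume that enters
`VRR = 100 x ablated / initial` is the volume of nodule elements with
`D >= 1` (theta >= 63.2 %, the conventional coagulation threshold);
the threshold and a fractional `int theta dV` variant are configurable.
With the thyroid/nodule pair `A = 7.39e39 1/s`, `dE = 2.577e5 J/mol`, the
damage rate at body temperature is ~2.9e-4 1/s — a non-negligible baseline
drift (D ~ 0.35 over 20 min at 37 degC). That is what the reference
constants imply; we keep it by default and expose a temperature cutoff
(`T_cutoff`) that zeroes sub-threshold accumulation for sensitivity
studies. The drift stays below the D = 1 ablation threshold, so it does
not by itself create VRR.

### Perfusion-damage coupling: an important default

The damage-decayed perfusion law is implemented and unit-tested, but by
default it is **not** wired into the Pennes sink (`perfusion_decay=False`).
Rationale: the Arrhenius pair above destroys (D >= 1) any tissue held
above ~43 degC for 20 min, so a damage-gated perfusion shutdown makes the
heated front self-accelerating — in our experiments the entire 20 mL
nodule is ablated within ~5 min at 60 W and the 10 mm shell exceeds
250 degC. Every known property of this treatment regime — VRR near 65 %
after 60 W x 20 min, damage confined near the electrode, nodule periphery
near body temperature, sub-100 degC at 10 mm, and a visible difference
between nodule perfusion scenarios — requires the perfusion sink to remain
active in heated tissue. With the baseline-perfusion sink the model
reproduces that regime (e.g. peak-temperature ratio between 5 mm and
40 mm tips ~2.9; shell maximum 87 degC at 60 W x 1200 s with the 10 mm
tip on the coarse mesh). Setting `perfusion_decay: true` restores the
fully coupled variant for comparison.

## Geometry and meshing

The neck phantom is a 120 x 80 x 80 mm block of stacked slabs along the
depth axis: skin 1 mm, fat 6 mm, muscle 30 mm, thyroid 20 mm, with deeper
tissue treated as muscle. The 20 mL nodule is a triaxial ellipsoid
(semi-axis ratios 20 : 15.9 : 15, long axis along the electrode, scaled to
the exact target volume); it locally bulges the thyroid slab, which a
20 mL volume cannot avoid, and overrides it where they overlap. The
18-gauge electrode (1.27 mm) is inserted along +x parallel to the XY
plane with its active tip centered in the nodule; the shaft continues to
the domain face.

The mesh is a graded structured hexahedral grid split into six tetrahedra
per cell (Kuhn split, conforming on structured grids). Grid planes snap to
every axis-aligned material interface, including the electrode channel, so
the conductor is represented as a square prism of exactly 1.27 mm width at
any resolution. Cell size grows geometrically away from the tip. Presets
are calibrated by element count — `fine` ~1e5 tets (the reference
resolution), `medium` ~6e4, `coarse` ~3.5e4, and a desk-scale `tiny`
(~9e3) used by the fast tests; all are deterministic. The analytic
impedance oracle uses a separate cube-sphere shell mesh with a true
spherical electrode surface (each hex split through face/cell centroids,
which keeps the seams conforming).

Consequences of the square-prism electrode: the effective electrode
perimeter is ~13 % larger than the circular needle, and on coarse grids
the near-field Joule deposition is smeared over the first one or two cell
layers. Total delivered power is exact by construction (power control
rescales the discrete solution), so far-field temperatures are much less
resolution-sensitive than the peak temperature at the tip, which grows
with refinement (165 -> 293 degC between the tiny and coarse presets in
the 10 mm/60 W case). Absolute impedance is similarly coarse-mesh-biased
low; impedance *ratios* (roll-off percentages) are more robust.

## Time integration

Backward Euler with fixed `dt` (default 1 s, 0.25-5 s supported),
first-order operator splitting per step: (1) update `sigma(T)`, `k(T)`,
perfusion from lagged fields; (2) electric solve + power rescale;
(3) implicit thermal step; (4) damage accumulation with the rectangle rule
on end-of-step element-mean temperatures (trapezoid optional). The thermal
step matrix is refactorized only when its coefficients have drifted more
than 1 % (configurable), mirroring the electric-side property lag; mass
and sink terms are lumped, keeping the step matrix an M-matrix
(unconditionally stable, monotone). Verified orders: ~2 in space (P1,
manufactured solution), ~1 in time (exponential relaxation oracle,
tau = rho c_p / (rho_b omega_b c_b) ~ 10.2 s for thyroid).

## Planning problem

Objective `(VRR - 65)^2` over the box 45-60 W x (0, 1200] s, with the
safety rule — temperature below 100 degC everywhere beyond 10 mm from the
needle surface — as a smooth quadratic exterior penalty. The penalty form
and its weight (10 (degC)^-2(%)^2 by default) are our design choices: the
clinical rule only names the bound, not how an optimizer should enforce
it. The safety monitor samples a deterministic
capsule-offset shell (cylinder plus distal hemispherical cap, ~1 mm
spacing) via cached P1 interpolation weights.

The solver is COBYQA (scipy), a quadratic-model trust-region
derivative-free method with box bounds, the same family as BOBYQA.
Variables are scaled to [0,1]^2; start at the box center, initial trust
radius 0.25, final 1e-3, budget 60 evaluations; a `1e-6 t_scaled`
regularization breaks VRR(t)-plateau ties toward shorter treatments.

Because a constant-power treatment is non-adaptive, one full-horizon run
yields the whole `VRR(t)` trajectory; duration is read off the stored
trace. Power is additionally discretized to a 1 W grid — the setpoint
resolution of clinical RF generators — with linear interpolation between
the two bracketing grid runs, so one planning solve costs a handful of
forward runs instead of sixty. A literal truncated re-run agrees with the
lookup to well under 0.5 VRR points (tested).

## What the phantom does and does not emulate

The phantom reproduces the layered composition, nodule volume, electrode
geometry, and the reference property tables; it does not include curved
thyroid lobes, heterogeneous tissue properties, large-vessel advection,
tissue shrinkage, water vaporization (temperatures may exceed 100 degC
near the tip), or generator impedance-roll-off shutoff logic. Passing
tests therefore demonstrate correctness of the stated model on an
idealized geometry, not clinical predictive accuracy.

## Desk-scale test sizes

The shipped test suite runs the transient model on the `tiny` preset
(~9e3 tets, dt = 2 s) for trend checks and planning cells, and on the
`coarse` preset (~3.5e4 tets) for the quantitative impedance/safety
checks; the acceptance script uses `coarse`. `medium`/`fine` reproduce
the same trends with sharper near-tip peaks and slightly higher
impedance.

## Known limitations

* Printed planning-time targets (e.g. ~9 min minimum at the 30 mm tip)
  assume VRR dynamics slower than this model produces: with the reference
  Arrhenius constants the D >= 1 front reaches 65 % of the nodule well
  before 20 min at 45-60 W in every scenario, so the planner reports
  shorter optimal durations and does not saturate at the box corner in the
  high-perfusion case. See the damage-kinetics discussion above.
* The energy trace is exactly `P x t` under constant-power control; no
  duty-cycling or roll-off throttling is modeled.
* The square-prism electrode and structured grading trade near-tip
  resolution for robustness and determinism; peak temperature is the most
  resolution-sensitive output.
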