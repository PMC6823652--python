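# Methods

This note records the models, numerical choices and conventions behind
`lyosim`, in enough detail to reproduce or audit any number the package
computes.

## Freezing model

The product (mass `rho*V`, specific heat `Cp`) is a single thermal node
coupled to the shelf through a film coefficient `h` acting over the vial
cross-section `Av`:

    rho * Cp * V * dTpr/dt = -h * Av * (Tpr - Tsh(t)).

Three stages are chained:

1. **Liquid cooling** with `Cp = cp_liquid` until `Tpr <= Tn`. Nucleation is
   *not* modeled — `Tn` and `Tf` are required inputs, reflecting the
   stochasticity of uncontrolled nucleation.
2. **Crystallization hold**: `Tpr` jumps to `Tf` and stays there while the
   latent budget `rho*V*(Hf - cp_liquid*(Tf - Tn))` is removed at the
   instantaneous rate `h*Av*(Tf - Tsh(t))`. For constant `Tsh` this reduces
   to the closed form `dt = budget / (h*Av*(Tf - Tsh))`, which the
   integration reproduces to within one time step.
3. **Solid cooling** with `Cp = cp_ice` to the end of the schedule.

Integration is explicit Euler with `dt = 1e-3 h` by default; halving the
step changes stage durations by well under 0.5%. The model is only as good
as the lumped-capacitance assumption: for water fills the cooling-stage Biot
number (characteristic length = max of fill height and vial diameter) is
~0.6, and `biot_number` warns above 0.1. Expect the crystallization hold to
be overpredicted relative to thermocouple data (the interface is not
isothermal in reality); the model is meant for cycle design with a safety
factor, not for thermal metrology.

`fit_film_coefficient` estimates `h` by nonlinear least squares (on `log h`,
Levenberg–Marquardt) against the pre-nucleation segment of a measured
trace, simulating stage 1 alone at each candidate.

## Primary-drying model

Quasi-steady 1D balance per time step; symbols as in the README. The two
conduction legs are a series conductance

    U = 1 / (1/(Kv*Av) + Lpr/(k_ice*Ap)),

leaving one scalar equation in the front temperature `Tsub`:

    U*(Tsh - Tsub) = dHs*Ap*(Psub(Tsub) - Pch)/Rp(Lck).

The left side falls and the right side rises strictly with `Tsub`, so the
root is unique; it is found with Brent's method at near machine tolerance
(`xtol = 1e-12 K`), after which the three legs agree to better than 1e-9
relative — an invariant asserted in the tests. Special cases: if the vapor
pressure of ice at shelf temperature is below `Pch`, no sublimation is
possible and the zero-flux fixed point (product equilibrated with the
shelf) is returned; when `Lpr < 1e-9 cm` the conduction leg is dropped and
`Tbot = Tsub`.

**Front advance.** `dLck = flux*dt/rho_ice`, with the initial frozen length

    Lpr0 = Vfill/(Ap*rho_ice) * (rho_solution - csolid*(rho_solution - rho_ice)/rho_solute),

so the total sublimated mass per vial is `rho_ice*Ap*Lpr0`. The same
ice-density basis is used in both places; this convention (rather than a
water-mass basis) is what the published drying-time tables for these models
imply, and mass conservation against it is asserted to 1e-9.

**Stepping.** Default `dt = 0.05 h` (3 min). The last step is interpolated
linearly in cake length, and drying times are quoted to 1e-3 h. The
legacy "product-length divisions" scheme (`simulate_primary_drying_by_divisions`)
advances in `Lpr0/n` cake increments with the flux frozen at each segment
start; because flux falls monotonically under constant setpoints, coarse
divisions always underestimate the drying time, converging to the
time-stepped result from below (within 0.5% at 1e4 divisions).

## Physical constants

| quantity | default | units | note |
|---|---|---|---|
| dHs (ice heat of sublimation) | 650 | cal/g | see below |
| k_ice (frozen-layer conductivity) | 0.0059 | cal/s cm K | ~2.5 W/m K |
| Hf (heat of fusion) | 79.7 | cal/g | |
| cp_liquid / cp_ice | 1.0 / 0.503 | cal/g K | |
| rho_ice | 0.918 | g/cm^3 | |
| vapor pressure of ice | 2.698e10 * exp(-6144.96/T) | Torr, T in K | |

All are overridable through `PhysicalConstants` / the `constants:` config
block. The vapor-pressure correlation is the standard one in primary-drying
models; it matches the ice triple point (4.58 Torr at 273.15 K) within 1%.
`dHs = 650 cal/g` is the value used in the classic vial freeze-drying
models this package follows (the modern calorimetric value is ~678 cal/g =
2838 J/g); the lower value keeps the package consistent with the published
drying-time tables in that lineage, and sensitivity is linear — drying
times scale roughly with `dHs`, about +3% at 678.

**Areas.** `Av` (shelf heat transfer) uses the vial *outer* diameter, `Ap`
(sublimation and conduction) the *inner* diameter, following the vial
heat-transfer literature. **Units.** Internal computation is entirely in
the practical system (cm, Torr, cal, g, h; tabulated coefficients per
second are rescaled by 3600 internally); `convert_units` handles the
SI equivalents, with the thermochemical calorie (4.184 J) and
1 Torr = 101325/760 Pa, which reproduces the dual-unit coefficient tables
in the literature to their printed precision.

## Calibration modes

* `fit_kv_to_drying_time`: drying time is strictly decreasing in `Kv`, so a
  bisection on `[1e-5, 1e-2] cal/s K cm^2` matches the target time to
  1e-3 h. Unreachable targets raise with the achievable range.
* `fit_kv_pressure_curve`: bounded (nonnegative) least squares of the
  three-coefficient curve; with exactly three distinct pressures the fit
  interpolates (checked to 1e-8 on synthetic data). `KD -> 0` degenerates
  gracefully to the linear model.
* `rp_profile_from_temperature`: walks the measured `Tbot(t)` through the
  balance algebra — heat from the `Kv` leg, flux from `dHs`, `Tsub` from
  conduction, `Rp` from the vapor-pressure drop — advancing `Lck` with the
  running flux integral (self-consistent, not an assumed schedule). Samples
  with nonpositive flux or `Psub <= Pch` are dropped with a warning.
* `fit_rp_curve`: nonnegative least squares of `(R0, A1, A2)`.

## Design space and optimizer

The design space evaluates the balance over a `(Pch, Tsh)` grid at a fixed
drying stage (cake-length fraction; "end-of-drying" is the conservative
convention since `Rp` is then largest). The critical product-temperature
curve pins `Tbot = Tpr,max`: the conduction/sublimation legs then determine
`Tsub` and the flux, and the shelf temperature required to deliver that heat
is backed out of the `Kv` leg. Note that at fixed pressure this required
shelf temperature *falls* as the cake grows — the admissible flux falls
faster than the resistance demands heat — which is why end-of-drying optima
sit below the shelf ceiling.

`optimize_step` maximizes flux over `Pch` for the current cake length. At a
candidate pressure the best admissible shelf temperature is
`min(tsh_max, tsh pinning Tbot = Tpr,max)`; if the implied batch rate
exceeds the capability line `a + b*Pch`, the flux is cut to the capability
and the sustaining shelf temperature is recovered in closed form (if that
temperature would exceed the ceiling, the ceiling itself governs). The
pressure search is a 40-point log-spaced scan plus golden-section
refinement; the flux-in-pressure profile is unimodal on the shelf-ceiling
branch (verified against exhaustive 2D scans in the tests), and ties or
plateaus resolve to the lower pressure (cheaper vacuum). Single-variable
modes hold the other setpoint at its schedule value; in pressure-only mode
pressures whose quasi-steady `Tbot` exceeds the limit are simply
inadmissible, and the optimum typically sits on that feasibility boundary,
located by the same refinement. The control interval defaults to 0.05 h.

Binding-constraint tags (`Tpr-max`, `Tsh-max`, `Pch-min`, `Pch-max`,
`equipment`) are recorded per step; with a binding capability line the
expected sequence — flux pinned at the equipment limit with the shelf
warming, then handover to the product limit — is asserted in the tests on a
synthetic capability line chosen to cross the product-limit flux mid-cycle.
The equipment constraint treats all vials as identical center vials.

## Synthetic data

`generate_synthetic_profile` produces thermocouple-like traces by forward
simulation plus seeded i.i.d. Gaussian noise (default sd 0 °C; calibration
tests use 0.1–0.3 °C, typical of thermocouple scatter). It emulates
sampling density and sensor noise only — not sensor bias, edge-vial
heterogeneity, shelf-surface temperature excursions, or the stochastic
nucleation that dominates real freezing data. Passing recovery tests on
these traces therefore demonstrates correctness of the inverse algebra and
fit machinery, not robustness to real-world systematics.

## Problem sizes

The test suite and the acceptance script run the study conditions directly:
2 mL fills in 6R vials (~250 time steps at 3 min), the slow 8 mL / 5800W
cycle (~120 h simulated, still ~1 s of wall time), optimizer cycles of
40–110 control intervals, and exhaustive oracles at 150x150 (step
optimizer) and 400–800-point scans (design-space optima). The full suite
runs in under 10 s on one CPU.

## Known limitations

* Center-vial model: no edge-vial/radiation heterogeneity; batch rate is
  `n_vials` times the center vial.
* No secondary drying, condenser dynamics, or choked-flow computation (the
  capability line coefficients are inputs).
* `k_ice`, `dHs`, `Cp` are temperature-independent.
* No stochastic or controlled nucleation model; `Tn`, `Tf` are inputs.
* The quasi-steady drying model has no thermal mass: step changes in
  setpoints take effect within one control interval.
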