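# Methods

## Model structure and assumptions

The system couples a well-mixed tank (CSTR) to a one-dimensional biofilm
of uniform thickness `L_f(t)` on a surface of area `A`. Two particulate
species (live `L` and dead `D` biomass) and two solutes (glucose `G` and
hydrogen peroxide `H`) are tracked in both compartments. Assumptions:

- The film is laterally homogeneous; all gradients are normal to the
  substratum (`z = 0`) with the film–liquid interface at `z = L_f`.
- Growth is Monod in glucose only; HP does not inhibit growth directly,
  it only converts live to dead biomass (first order in each of HP and
  live biomass, rate coefficient `k_dis`). Killing conserves biomass.
- Catalase activity is constitutive and survives cell death: both live
  and dead biomass neutralize HP with coefficients `k_B:L`, `k_B:D`.
  There is no adaptive induction, dormancy or persister state.
- Particulates move only by growth-induced advection with velocity
  `v(z)` (the cumulative volumetric production below depth `z` divided by
  the local total volume fraction `P_tot`); solutes move only by
  molecular diffusion. Attachment of suspended cells to the film is
  neglected (relevant to early colonization, not mature persistence).
- Detachment erodes the surface at `v_det = K_det L_f²`, returning
  particulates to the tank.
- Solute exchange with the tank passes through a stagnant boundary layer
  of thickness `L_L` with aqueous diffusivities; inside the film reduced
  diffusivities `D_b` apply.

Because `v(z)` divides by `P_tot` and the advection balances the local
production exactly, the total particulate volume fraction remains at its
initial value (0.08) in every cell at all times; this invariant is the
primary correctness check of the velocity/advection pairing and is
asserted in the tests to 1e-3 relative.

## Parameters

Defaults (all in m / day / g·m⁻³ units) are the standard set:
`mu_max = 9.6 d⁻¹`, `K_M = 5 g/m³`, `Q = 1 m³/d`, `V = 0.1 m³`,
`A = 1 m²`, `k_dis = 0.5 (g_H/m³)⁻¹ d⁻¹`, `Y_GL = 0.26`,
`S_in_G = 100 g/m³`, `k_B_L = k_B_D = 10`, `rho_L = rho_D = 2.5e5 g/m³`,
`D_b_G = 1.3e-5`, `D_b_H = 6.52e-5`, `D_aq_G = 5.2e-5`,
`D_aq_H = 1.09e-4 m²/d`, `L_L = 1e-5 m`, `K_det = 1e4 m⁻¹d⁻¹`,
`Lf0 = 50 µm`, initial live volume fraction 0.08, `Nz = 50`,
`t_final = 100 d`. With these values the untreated film reaches a steady
thickness near 140 µm within about two days, set by the balance
`v(L_f) = K_det L_f²`.

A unit note on `k_B`: the neutralization law `R_S:H = −k_B S_H X` is
dimensionally consistent only if `k_B` carries units of
per-(g biomass/m³) per day, although the coefficient is conventionally
quoted as `(g_H/m³)⁻¹ d⁻¹`. We implement the rate law exactly as written
with the numeric value 10; only the product `k_B·X` (≈ 2×10⁵ d⁻¹ inside
the film) matters to the dynamics.

## Discretization and numerics

The moving domain is mapped to `ζ = z/L_f ∈ [0, 1]` with `Nz` uniform
cells, keeping the ODE system size fixed. The chain rule introduces
`1/L_f` (first derivatives), `1/L_f²` (second derivatives) and a
grid-motion advective term proportional to `ζ·dL_f/dt`, which is applied
to particulates and solutes alike.

- **Particulate advection**: conservative first-order upwind on the
  relative face velocity `w = v − ζ·dL_f/dt` plus the dilation term
  `−(dL_f/dt / L_f)·X`. The base face carries zero flux; at the surface
  `w = v_det ≥ 0`, so material leaves only by detachment and the discrete
  detachment flux equals `v_det·X_b(top)` exactly. Upwinding is
  positivity-preserving; the profiles are smooth at `Nz = 50`.
- **Solute diffusion**: central second differences. Zero gradient at the
  base; at the surface the interface concentration is eliminated by
  matching the in-film flux `D_b (S_s − S_top)/(Δz/2)` to the
  boundary-layer flux `D_aq (S_t − S_s)/L_L`, which also furnishes the
  tank exchange flux `J_dif`. The operator is validated against the
  closed-form `cosh(z/λ)` profile of first-order consumption to within
  1% at `Nz = 50` (5×10⁻⁴ at `Nz = 400`).
- **Integration**: scipy `solve_ivp` BDF with `rtol = 1e-6`,
  `atol = 1e-8`. Stiffness comes from HP neutralization
  (`k_B·X_b ~ 2×10⁵ d⁻¹`). The integrator is restarted at the dosing
  switch times so the influent discontinuities are never stepped over.
  Negative concentrations that appear transiently within solver tolerance
  are clamped to zero inside rate evaluations only; the state is not
  mutated.
- **Thickness floor and eradication**: `1/L_f` factors are guarded by a
  floor of 1e-8 m; a terminal event stops the run when `L_f` falls below
  2e-7 m, and a run whose final thickness is below 1 µm with a
  non-positive trend is flagged eradicated. 1 µm is far below any
  surviving steady state, and eradication is reported as a normal
  terminal outcome.
- **Steady state**: declared when the relative drift of both `L_f` and
  areal live biomass over the final 10% of the horizon is below 1e-3;
  otherwise the horizon is doubled (resuming from the final state) up to
  2000 days. The interior live/dead composition of a dosed film
  equilibrates much more slowly than the thickness, so stratification
  metrics use an explicit 2000-day horizon.

HP is consumed so fast inside the film (`λ = sqrt(D_b:H/(k_B X_b)) ≈
0.6 µm`) that its profile is sub-grid at `Nz = 50`: the kill zone is
effectively the top cell. The integrated kill rate is nevertheless
well-behaved — it is controlled by the HP flux into the film times
`k_dis/k_B` — and the thickness is grid-stable (<1% change from `Nz = 50`
to 200), but HP-profile *shapes* at default resolution are indicative
only.

## Metric definitions

Where the headline quantities admit more than one reading, the package
fixes these defaults (all exposed as plain functions/arguments):

- **Areal biomass**: midpoint integration of `X_b` over depth, g/m².
- **Percent live**: areal live over areal total; **mean live fraction**:
  unweighted depth average of the local live fraction. With equal
  densities both are volume-fraction readings.
- **Log reduction at steady state**: `log10(reference/treated)` with the
  untreated steady-state areal live biomass as reference.
- **1-day viability log reduction**: `−log10` of the viable fraction
  (live over total areal biomass) at the end of the exposure day. At dose
  onset the film is all-live, so this counts the cells killed and
  retained over the interval; the alternative onset-over-endpoint ratio
  of live biomass is negative during the first treatment day because the
  film is still growing, and is available via `log_reduction`.
- **Planktonic comparison**: closed form `k_dis·S_H·t/ln 10` from
  `dX/dt = −k_dis S_H X` at the simulated mean bulk HP concentration.
- **Penetration depth**: depth below the surface where a solute profile
  first falls under 5% of its surface value (linear interpolation between
  cell centers; configurable threshold). The 5% default reproduces the
  "essentially depleted" character of the deep film.

## Scenarios and searches

Cases: A untreated; B continuous 500 g/m³ HP from day 2; C on at day 2,
off at day 6; D dose sweep; E only dead-cell neutralization
(`k_B_L = 0`); F only live-cell neutralization (`k_B_D = 0`); G influent
glucose sweep. Continuous treatment is encoded as `dose2 = dose1` so it
never ends; every sweep point starts cold from the standard initial
condition (each dose is an independent simulation, not a continuation).
Threshold searches bisect a monotone predicate ("eradicated",
"thicker than untreated") to a resolution of 100 g/m³ on dose axes and
1 g/m³ on the glucose axis, running every candidate to the steady-state
criterion.

## Known limitations

- First-order upwinding adds numerical diffusion to the live/dead
  interface; stratification boundaries are smoothed by a few cells.
- The HP kill layer is unresolved at default resolution (see above);
  quantities that are *differences* of nearly equal thicknesses (e.g. the
  percent thickness reduction just below the eradication threshold)
  inherit amplified sensitivity to the spatial scheme, of order a few
  percentage points.
- The model omits adaptive catalase induction, dormancy, EPS mechanics
  and attachment; it is a mechanistic minimal model, and passing its test
  suite demonstrates internal consistency with that model, not agreement
  with any particular experimental biofilm.
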