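# Methods

## Model

A reaction network is a list of species and irreversible reactions with
integer stoichiometry.  Two rate-law kinds are supported:

* **mass action** — `v = k * prod_i [R_i]^m_i` with `m_i` the stoichiometric
  multiplicity of reactant `R_i`; `k` carries units `M^(1-order) s^-1`.
* **empirical autocatalytic** — `v = k_direct * prod [R_i]^m_i +
  k_auto * prod [R_i]^m_i * [C]^p` for a designated autocatalyst C and a
  kinetic order `p > 0` that may be fractional.  `0^p` is defined as 0
  (continuity from the right) so trajectories may start at `[C] = 0`.

Concentrations are molar and time is in seconds throughout; there is no unit
conversion layer, matching the units of all built-in rate coefficients.

The batch ODE is `dc/dt = S v(c)` with `S` the species-by-reactions net
stoichiometric matrix.  Flow (CSTR) adds the standard balance
`k0 (c_feed - c)` applied to **every** species: reagents enter at their feed
concentrations, everything flows out at the same rate `k0`, and the
residence time is `tau = 1/k0`.  The source text of the underlying study
names only the inflow/outflow rate `k0`; the standard CSTR balance is
adopted here, and the feed is set equal to the batch initial composition
(reagents at 1.0 M, products absent), consistent with the study's statement
that initial and feed concentrations of the reagents do not differ.

Reversible steps are stored as two irreversible reactions; an equilibrium
constant is a derived quantity (e.g. K = kII/kIII = 0.01 M^-1 for the
supercatalysis pre-equilibrium).

## Mechanism families and parameter provenance

All presets encode printed parameter sets verbatim (see the `notes` field of
each preset).  Two clashing rate-constant numbering schemes exist for the
hypercycle in the source material; this package uses role-based names
(`kAB_direct`, `kBC_auto`, `kAD_fast`, `kXY_direct`, `kYZ_auto`, `kXW_fast`,
`kAZ_cross`, `kAZB_fast`, `kXC_cross`, `kXCY_fast`) and documents the
mapping table in `cyclekin.models`.  The caption-order scheme (fast steps
k3 = k5 = k8 = k10; cross steps k4, k9) is the one consistent with the
printed decoupling statement "k4 = k9 = 0 makes the cycles independent",
and it is corroborated numerically: under it the option-B value
k9 = 0.093 M^-1 s^-1 makes the batch induction periods of C and Z coincide
to 0.01 s — a finely tuned coincidence that no alternative reading
reproduces.

Sweep constraints are solved exactly: the Landolt sweep stores the twelve
printed `k2/k1` ratios with `k1 k2 = 1e-5 M^-2 s^-2`, the supercatalysis
sweep the seven printed `kIV/kI` ratios (verbatim, including their
non-monotone order) with `kI K kIV = 1e-5 M^-3 s^-2`.

## Numerics

* **Integrator.** Rate coefficients span ~20 orders of magnitude
  (1e-13 … 1e8), so all integrations use `scipy.integrate.solve_ivp` with
  the BDF method and an **analytic Jacobian** `S dv/dc (- k0 I under flow)`.
  Defaults `rtol = 1e-8`, `atol = 1e-12 M`; reported selection ratios change
  by < 1e-4 under a further 10x tightening (tested).
* **Negative concentrations.** Solver states are clipped to 0 before rate
  evaluation; any accepted state below -1e-9 M aborts the run.  Dense-output
  interpolants between accepted steps may legitimately overshoot slightly
  and are clipped without aborting.
* **Jacobian at [C] = 0 with p < 1.** The singular derivative of `[C]^p`
  is replaced by 0; Newton iterations inside BDF only need an approximate
  Jacobian and the direct-term dynamics dominate there.
* **Batch output grid.** Adaptive solver steps, densified (25 extra points)
  around each species' maximum-slope interval so steep sigmoid ignitions
  are resolved in the stored trajectory.
* **Steady states.** Integrate the CSTR ODE from the batch initial state in
  geometrically growing spans (>= one residence time each) until
  `max|dc/dt| < 1e-12 M/s` at two checkpoints one residence time apart, up
  to `t_max = 1e3/k0`; then polish with damped Newton (`scipy.optimize.root`,
  hybr, analytic Jacobian).  A polished root is accepted only when it is
  nonnegative and within 1e-6 (relative) of the integration endpoint, so
  polishing cannot jump to a different branch.  Near the ignition threshold
  (`k2 [B] ~ k0`) critical slowing can exceed `t_max`; such points are
  flagged `converged=False` and sweeps continue past them.  Autocatalytic
  CSTRs can in principle be bistable: the reported state is the one reached
  from the stated initial condition, and `sweep_flow(continuation=True)`
  re-seeds each point from its predecessor to probe hysteresis (none was
  detected for the bundled presets — all probed initial states, from the
  empty reactor to the fully converted batch, reach the same state).
* **Selection transition.** The transition flow rate is the first crossing
  of the ratio `r(k0)` through 0.25 (midpoint of a 0.5 -> 0 collapse),
  interpolated linearly in `log10 k0`; the sweep default is 25 points per
  decade.
* **Induction period.** Default is the tangent construction standard in
  clock-reaction kinetics: the tangent at the point of maximum slope
  extended to the time axis.  A threshold variant (first crossing of a
  conversion fraction, default 5%) is available for sensitivity analysis.
* **Conservation laws.** Computed by exact rational elimination (sympy
  nullspace of S^T over Q), scaled to primitive integer vectors, so the
  invariant `w . c(t) = const` can be tested without floating-point rank
  decisions.  The test suite checks them against an independent
  Fraction-arithmetic Gaussian elimination oracle.

## Problem sizes

Bundled analyses are small by construction: networks of 3–10 species and
1–10 reactions, batch horizons of 1e2–1e7 s model time, and flow sweeps of
~100 steady-state solves (25 points per decade over four decades).  Each
steady state costs well under a second with the analytic Jacobian.

## What the built-in scenarios do and do not show

The presets emulate idealised well-stirred reactors with exact rate
coefficients, equal 1.0 M reagent feeds and noise-free flow.  Passing tests
therefore demonstrate the internal consistency of the mechanistic picture —
parametrisation (k_auto/k_direct), not the formal autocatalyst order,
governs sigmoid character; flow rate selects among coupled autocatalytic
loops — but say nothing about real chemical systems, where side reactions,
temperature dependence, concentration fluctuations and imperfect mixing all
perturb the selection boundary.

## Known limitations and open points

* The full supercatalysis mechanism and its pre-equilibrium reduction agree
  analytically in their rate laws, but the full model sequesters the
  fraction `K [B] ≈ 1%` of the autocatalyst as BC, retarding its ignition
  clock by ~1% in time.  For the steepest printed parameter sets
  (kIV/kI >= ~1e4) this small shift maps to a large sup-norm difference in
  `[C](t)` during the near-vertical rise (up to ~55% of the final value at
  kIV/kI = 1e7, converged with respect to solver tolerance); for
  kIV/kI <= ~1e3 the curves agree within ~1%.  The reduction is a
  rate-law identity, not a trajectory identity.
* At flow rates far beyond the joint extinction of both autocatalysts, the
  selection ratio tends to the ratio of the direct seeding rates
  (`k6/(k1+k6) ≈ 0.91` for the base hypercycle) because both concentrations
  vanish while their quotient stays finite.  Selection statements are
  therefore made on the regime where a non-trace amount of autocatalyst
  survives (steady-state `[C]+[Z] > 1e-3 M`).
* The option-C winner share at `log10 k0 = -1.1` computes to ~65% under the
  printed parameters and the standard CSTR balance (robust to tolerance,
  protocol and every defensible parameter reading); the undershoot
  extremum does sit at `log10 k0 ≈ -1.1`.  A cross coefficient
  k9 = 0.003 instead of 0.03 would deepen it past 80%.
* No stochastic (Gillespie) simulation, no spatial/compartment models, no
  temperature dependence, no parameter fitting; SBML export is not
  provided — the YAML mechanism format is the interchange representation.
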