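# Methods

## Physical model

The package treats EZ formation as screened electrostatic repulsion in an
electrolyte. Three assumptions define the model:

1. **Mean-field, linearized electrostatics.** The potential around the
   charged body satisfies the linearized Poisson–Boltzmann equation for a
   monovalent symmetric salt (KCl), so every profile decays on the Debye
   length λ_D = √(ε_0ε_rk_BT / 2N_Ac_se²). Linearization is formally
   valid for |V| < k_BT/e ≈ 25 mV; the tubulin surfaces at 10 mM violate
   this at contact (−388 mV for the microtubule), which is known to
   overestimate |V| at low salt. The package logs a warning per affected
   scenario rather than failing: the point of the model is the length and
   time scaling, which the linear theory captures.
2. **Stern-layer offset.** A layer of adsorbed counterions of thickness
   d = 0.33 nm (one K⁺ radius) separates the surface from the diffuse
   layer; the Gauss-law boundary condition is applied at R+d (or x = d for
   the plane), and the solution is undefined inside it (`DomainError`).
3. **Deterministic overdamped motion.** The probe follows
   m·ẍ = Q_eff·E(x) − ξ·ẋ with ẋ(0) = 0. The thermal force is omitted,
   making runs deterministic; thermal displacement over the µs horizon is
   comparable in scale, so the output is the systematic (drift) component
   of the EZ, not an ensemble average.

### Geometry solutions

| geometry | potential | notes |
|---|---|---|
| cylinder | ∝ K₀(r/λ_D) | microtubule, R = 12.5 nm, σ = −0.102 C/m² |
| sphere | ∝ e^(−r/λ_D)/r (Yukawa) | tubulin dimer, R = 2.71 nm, σ = Q_bare/4πR² |
| plane | ∝ e^(−(x−d)/λ_D) | tubulin sheet, same σ as the sphere |

The spherical solution is implemented through the half-integer-order
modified Bessel functions. Two transcription choices were forced on us and
are verified by oracles rather than trusted:

- the auxiliary function g(z) appearing in the spherical field is
  implemented as a function of z alone (a stray r in one printed factor is
  treated as a typo for z); with that reading
  g(z) = −d/dz[z^(−1/2)K_{1/2}(z/λ_D)] exactly, which is what E = −dV/dr
  requires. The test suite enforces E = −dV/dr by central differences
  (rtol 1e−6) on 200 randomized scenarios and checks the whole spherical
  solution against the independently derived Yukawa closed form at rtol
  1e−10, so any misreading would fail loudly.
- half-order Bessel functions use their exponential closed forms
  (K_{1/2}(x) = √(π/2x)·e^(−x), K_{3/2} = K_{1/2}(1+1/x)); integer orders
  use scipy's exponentially scaled `k0e`/`k1e`. All Bessel *ratios* are
  assembled from scaled functions plus an explicit e^(−(r−r₀)/λ_D) factor,
  so profiles stay finite out to r/λ_D ~ 700.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| ε_r | relative permittivity | 78.3 | — |
| T | temperature | 293.15 (20 °C) | K |
| η | viscosity | 1e−3 | Pa·s |
| c_s | KCl concentration | 10 or 160 | mM |
| R | MT outer radius / dimer radius | 12.5 / 2.714 | nm |
| d | Stern-layer thickness | 0.33 | nm |
| σ | surface charge density | −0.102 (MT), −0.0903 (sphere/plane) | C/m² |
| a | probe radius | 2.714 | nm |
| Q_bare | probe bare charge | −52 | e |
| Q_eff | probe effective charge | −17 (10 mM), −29 (160 mM) | e |
| m | probe mass | 110 | kDa |

Notes on specific choices:

- **a = (2·2.5·4)^{1/3} nm = 2.714 nm**: volume equivalence of the dimer
  ellipsoid; this is the unique reading that reproduces the quoted
  2.71 nm radius.
- **σ for the sphere/plane is computed**, Q_bare/(4πR²) = −0.0903 C/m²,
  rather than stored as the rounded −0.090; the 0.3% difference is far
  below every tolerance used.
- **σ = −0.102 C/m² for the microtubule is a stored constant.** It is an
  area-weighted combination of the outer-wall charge (−25 e) and the two
  C-termini (−11 e each) per dimer, but the individual areas behind the
  weighting are not tabulated anywhere we could recompute from, so the
  combined value is taken as given. `mt_surface_charge` implements the
  weighting for users who supply their own area budget.
- **Q_eff is a per-concentration constant** reused across all three
  geometries; no interpolation is offered at other concentrations — a
  scenario at an untabulated c_s must state its probe charge explicitly.
- **m enters only the ps-scale inertial transient**; the default dynamics
  are overdamped, so the rough 110 kDa value is inconsequential.

## Numerics

- **Stiffness.** The inertial time m/ξ ≈ 3.6 ps versus µs–tens-of-µs
  horizons (ratio ~10⁷). Default integrator: LSODA via
  `scipy.integrate.solve_ivp`, rtol 1e−8; `mode="full"` integrates the
  second-order system, `mode="overdamped"` (the default) integrates
  ẋ = F(x)/ξ. The two agree to <1% displacement once t ≳ 10 ns; the
  residual deviation is the constant inertial deficit ~v₀m/ξ (~0.03 nm),
  which decays relative to the growing displacement.
- **Output grid.** 1200 logarithmically spaced samples from 1 ps to the
  horizon (plus t = 0): the motion is fast early and logarithmic late, so
  a log grid resolves both regimes and makes trapezoidal energy bookkeeping
  (friction work vs. potential-energy drop) close to ~1e−5 relative.
- **EZ definition.** Displacement from the initial position, matching how
  the time profiles are usually plotted ("relative distance"), not a
  potential-threshold crossing. Summaries report the EZ at the scenario
  horizon (default 50 µs) *and* at 10 µs, because quoted figures use both.
- **Force-law fit.** F/ξ = K·e^(−κx) is fitted by linear least squares on
  log(F/ξ) over trajectory positions with F > 1e−6·F(start) (avoiding the
  log of the vanished tail). For the plane the force is exactly
  exponential (κ = 1/λ_D, residual ~1e−15); for cylinder and sphere it is
  a tail approximation, within 10% of the true force over the first 5λ_D
  for the microtubule case.
- **Ties/degeneracies.** Q_eff = 0 yields a legal no-motion trajectory;
  fitting it raises `FitError`. Coordinates are validated against the
  Stern boundary with a 1e−12 relative slack to absorb unit-conversion
  roundoff.

## Synthetic scenarios

`ezmt.synthesis` samples media, surfaces and probes from ranges bracketing
the tubulin regime (c_s 1–500 mM and |σ| 0.01–0.2 C/m² log-uniformly —
they span decades; R 1–50 nm, a 1–10 nm, Q_eff −50…−1 e, T 273–320 K,
η 0.3–3 mPa·s, ε_r 40–90 uniformly), with one integer seed governing all
draws. These scenarios exist to property-test the machinery (gradient
consistency, screening monotonicity, integrator cross-checks) over a wide
physical envelope. They emulate parameter diversity only: all share the
idealized geometry, uniform charge, monovalent-salt and no-noise
assumptions, so passing tests demonstrate internal consistency of the
model across its parameter space — not agreement with real interfacial
water, where nonlinear screening, finite ion size, charge regulation and
Brownian motion all enter.

## Known limitations

- Linearized PB overestimates |V| (hence EZ sizes and energies) at 10 mM;
  the 160 mM results are closer to the nonlinear theory.
- No stochastic force: no dispersion estimate around the deterministic EZ
  curve, and no thermally activated re-entry.
- Idealized geometries (infinite cylinder/plane, uniform σ); no
  protofilament corrugation, C-termini dynamics, or hydrodynamic wall
  corrections to Stokes drag.
- The model's µm-scale experimental cousins (e.g. Nafion EZs) live on
  length scales the PB mechanism cannot reach; this package addresses the
  nm-scale biological regime only.
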