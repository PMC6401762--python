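# Methods

This note records the models implemented in `nanotransloc`, the
assumptions behind them, the defaults, and the numerical choices that a
user extending or trusting the package should know about.

## 1. Electrohydrodynamic engine (short stiff polymers)

### Geometry, units, sign conventions

A rigid cylindrical polymer (radius `a`, contour length `Lp`, surface
charge magnitude `sigma_p`) translocates coaxially through a cylindrical
membrane pore (radius `d`, thickness `Lm`, surface charge magnitude
`sigma_m`).  Both surfaces are anionic; charges are stored as positive
magnitudes and applied internally with negative sign.  The translocation
coordinate `zp` runs from 0 (tip at the pore mouth) to
`zex = Lp + Lm` (polymer fully escaped on the trans side).

Internal units: nm, seconds, kBT, elementary charge.  Electrostatic
potentials are dimensionless (thermal units kBT/e; converters to volts in
`constants`).  Voltage `delta_V` is V(trans) − V(cis); pressure
`delta_P` is P(cis) − P(trans); positive velocities are cis → trans.
Defaults: T = 298.15 K, water viscosity 8.91e-4 Pa s, eps_w = 80,
eps_m = 2 (the paper-standard room-temperature constants).

### Electrostatics

The annular field solves the linearized Poisson–Boltzmann (Debye–Hückel)
equation `phi'' + phi'/r = kappa^2 phi` on [a, d] with Gauss conditions
`phi'(a) = +4 pi lB sigma_p`, `phi'(d) = −4 pi lB sigma_m`.  The solution
is the Bessel pair I0/K0 with coefficients from the 2x2 boundary system,
evaluated through exponentially scaled Bessel functions so that large
`kappa d` never overflows.  A nonlinear PB boundary-value solver
(`pb_annulus_potential`, scipy `solve_bvp`) exists purely as a validation
oracle; the linear solution is the production path.  One-loop charge
correlations (multivalent-cation mobility inversion) are out of scope:
the engine is quantitative only for weak surface charges and monovalent
salt.

With `kappa = 0` and charged surfaces the annular Laplace problem is
overdetermined (a single flux constant cannot satisfy two independent
Gauss conditions of the same sign), so the solver requires salt whenever
a surface is charged and returns the zero field otherwise.

Two polymer–membrane interactions are implemented:

* **Mean field** (`barrier="mf"`): `Vp(zp) = −2 pi a sigma_p kBT
  phi_m(a) lp(zp)` — the in-pore polymer charge times the
  membrane-only potential at the polymer surface.  Linear in the pore
  occupancy `lp(zp)` (rise, plateau at `min(Lm, Lp)`, fall), repulsive
  for like-charged surfaces.
* **Image charge** (`barrier="image"`): the dielectric self-energy
  `beta dOmega(lp) = lp lB tau^2 * Int dq [2 sin^2(q lp/2)/(pi lp q^2)]
  Delta(q)` with the dielectric jump function `Delta(q)` of the
  low-permittivity membrane (`pb = sqrt(kappa^2 + q^2)`), evaluated by
  adaptive quadrature on [0, qmax], qmax = max(40/d, 20 kappa), relative
  tolerance 1e-8, with the analytic `q -> 0` limit
  `Delta(0) = K1(kappa d)/I1(kappa d)` substituted near the origin.
  The strong-salt limit `pi lB lp tau^2 e^(−2 kappa d)` is reproduced
  asymptotically; note it carries O(1/(kappa d)) corrections (≈10% even
  at kappa d = 8), so quantitative work at moderate salt should use the
  full integral.

The barrier is mapped onto the translocation coordinate as
`Vp(zp) = dOmega(lp(zp))`: the paper-level theory defines the
self-energy as a function of the in-pore length only, and composing it
with the piecewise occupancy is the minimal consistent embedding (the
plotted barrier then peaks over the occupancy plateau).  For transport
the self-energy is tabulated on 81 occupancy points and interpolated
with a monotone PCHIP spline.

### Hydrodynamics and transport

Stokes flow in the annulus gives the drift velocity
`v_dr = mu_e (dV/Lm)[phi(d) − phi(a)] + gamma a^2 dP/(4 eta Lm)` with
`mu_e = eps0 eps_w kBT/(e eta)` and the geometric factor
`gamma = d^2/a^2 − 1 − 2 ln(d/a)`; the bracket combines electrophoresis
and the opposing electroosmotic drag.  Diffusion coefficients:
`D = kBT ln(Lp/2a)/(3 pi eta Lp)` (bulk rod) and
`Dp(r) = kBT ln(d/r)/(2 pi eta Lp)` (in-pore), via one shared helper;
`Lp <= 2a` is a validation error for `D` while `Dp(d) = 0` is
legitimate (no-slip wall).

Steady-state observables are direct quadratures of the drift–diffusion
integral solutions with absorbing exit `c(zex) = 0` and source
`c(0) = c_cis` (default 1, results per unit cis concentration):

* capture rate: composite Simpson per potential segment;
* translocation time: reverse cumulative trapezoid for the inner
  integral (accumulated from the absorbing end — no catastrophic
  cancellation), log-domain outer weight; components tau1/tau2/tau3 from
  splitting the outer integral at the occupancy breakpoints, so the sum
  rule is exact by construction;
* density and mean velocity: log-domain Boltzmann weights normalized by
  their maximum (effective potentials reach ±100 kBT at α-Hemolysin
  parameters — every exponential is max-shifted, and a barrier above
  ~700 kBT honestly returns `inf` for the time).

Grids are segment-aware (kinks of the piecewise potential are segment
endpoints, never interior points), 4001 points per segment for
rates/times, 1500 for profiles.  Closed-form limits (flat potential,
pure drift, the high-salt and dilute-salt expansions of the drift
velocity) are used as cross-checks in the test suite, never as the
implementation.

Critical quantities (`critical_pressure`, `trapping_salt_densities`,
`critical_length`) are bracketed roots of the mean velocity over the
respective parameter, classified by the direction of the sign change;
the dimensionally consistent closed forms of the high-salt and
dilute-salt expansions are exposed alongside and agree with the roots to
~10–25% inside their validity regimes (kappa a >> 1 and << 1
respectively) — outside those regimes only the numerical roots are
meaningful.

## 2. IFTP engine (long flexible polymers)

Reduced units throughout: segment length, kBT and solvent friction per
monomer equal 1.  The translocation coordinate `s` obeys overdamped
Brownian dynamics `Gamma ds/dt = f_tot`, with iso-flux (spatially
uniform monomer flux) closure `phi = f_tot/Gamma` and effective friction
`Gamma = R + eta_p` (pore-driven) or `R + eta_p + s` (end-pulled; the
straightened trans-side subchain adds friction `s`).  Only the
strong-stretching regime is implemented (mobile subchain fully
straightened, `l = R`); trumpet and stem-flower regimes, semi-flexible
crossover and flickering pores are out of scope.

During tension propagation the front obeys
`dR/dt = c R^((nu−1)/nu) phi / (1 − c R^((nu−1)/nu))` with
`c = nu A_nu^(1/nu)`; the stage ends when `R + s = N0` and the front
then retreats at `dR/dt = −phi` until `s = N0`.  The printed
post-propagation front equation carries a `+phi` sign, but integrating
the front "from R(N0) to 0" with `s` increasing and mass conservation
pinned at `N0` forces the retreating sign; the solver integrates the
shrinking front.

Choices:

* **Initialization**: tension seeded with one segment — `s(0) = 0`,
  `R(0) = A_nu`.  This sits above the denominator singularity whenever
  `nu A_nu < 1` (checked; e.g. 0.676 for the default A_nu = 1.15,
  nu = 0.588) and costs an O(1/N0) relative offset against the
  closed-form times (0.2% at N0 = 128).
* **Entropic pore force** `(1 − gamma')[1/(N0 − s) − 1/s]` is available
  but off by default (negligible in strong stretching); it is singular
  at the chain ends and is evaluated with `s` clamped to [1, N0 − 1].
* **Stiff chains** (`chain="stiff"`): rodlike limit `R = N0 − s`, total
  friction constant at `N0 + eta_p`; the propagation stage is negligible
  and is skipped, reproducing `tau = (eta_p N0 + N0^2)/f` exactly.
* **Integration**: adaptive RK45 (rtol 1e-10) with terminal events for
  the stage switch and completion; deterministic runs expose dense
  `s(t)`, `R(t)` for waiting-time binning by root-finding at integer
  `s`.  Stochastic runs use fixed-step Euler–Maruyama (dt = 1e-3) with
  noise variance `2 Gamma kT dt` (kT = 1 by default), reflection at
  `s = 0`, mandatory seeds, and online accumulation of waiting-time
  bins.  The distributions for stochastic `f` and `A_nu` used in
  published stochastic-augmentation comparisons are not specified here
  and are left to the caller.
* **Waiting time** `w(k)`: time spent with `s` in [k−1, k).  Flat for
  stiff chains (friction exchange cancels), peaked at the TP→PP switch
  for pore-driven flexible chains, constant through PP for end-pulled
  chains.
* **Scaling fits**: least-squares slope in log-log after optional
  rescaling — `tau − eta_p N0/f` (pore friction removed; slope
  1 + nu = 1.588 for 3D self-avoiding chains) or additionally minus the
  cis integral `A_nu N0^(1+nu)/((1+nu) f)` (end-pulled trans-side
  remainder; slope 2).  Acceptance sweeps fit the largest decade of the
  N0 grid.  Exact power-law input is recovered to 1e-10.

## 3. Fixtures and what green tests establish

The packaged fixtures carry the published benchmark parameter sets
(solid-state pressure–voltage trapping; α-Hemolysin at 0.04/0.1 M; IFTP
waiting-time and scaling benchmarks).  The polymer radius for the
solid-state setup is not printed in its source and defaults to the
ds-DNA value a = 1 nm (flagged in the fixture note); the base pressure
and voltage of the scan fixtures are scan anchors, not measurements.

The test suite validates the engines against closed forms, independent
numerical oracles (finite-difference boundary-value solves, Riemann
sums, nonlinear PB, high-precision Bessel evaluation) and published
scaling exponents and barrier heights.  It does not validate against
experimental data: the experimental comparisons in the source material
(velocity/time vs pressure, mobility inversion by multivalent cations)
involve fitted parameters or out-of-scope correlation physics and are
deliberately not acceptance surfaces.

## 4. Known limitations

* Mean-field electrostatics only; no charge correlations, charge
  inversion or mobility reversal (multivalent counterions).
* Rigid-rod polymer in the electrohydrodynamic engine; quantitative only
  for Lp below ~the persistence length.
* Infinite-cylinder pore: no entrance/exit hydrodynamics or access
  resistance.
* IFTP: strong-stretching regime only; thin-pore approximation (no
  capture or escape stages, tau1 = tau3 = 0 in that engine's
  decomposition).
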