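# Methods

## The oscillator map

A single glycolytic oscillator is modelled by the sine-circle map without
rotation term,

    theta_{t+1} = theta_t + (kappa / 2 pi) sin(m pi theta_t),

iterated as a raw difference equation: no modular reduction is applied.
This matters for the lattice layer, where unbounded growth ("blow-up") is
a genuine, diagnostic behavior that wrapping would silently destroy.
Because the map commutes with integer shifts of theta, *classification*
of orbits is performed on fractional parts, with circular distance, so a
label is invariant under integer drift of the whole orbit.

Fixed points solve sin(m pi theta*) = 0, i.e. theta* = k/m. The
multiplier at the stable branch (cos(m pi theta*) = -1) is
1 - kappa m / 2, so the fixed point period-doubles at

    kappa_c = 4 / m        (kappa_c = 2 for the default m = 2).

`stability_boundary` returns this closed form; the tests confirm it by
locating the first non-period-1 grid point of a numerical kappa scan for
m in {2, 3, 4}. The harmonic m only rescales the cascade: m = 3, 4 move
the bifurcation points, nothing else.

Defaults: 10,000 iterations per orbit with the first 9,000 discarded as
transient, classification tolerance 1e-6, maximum searched period 64
(exhaustive p = 1..64, smallest period wins), blow-up bound |theta| >
1e6 or non-finite. The measured cascade for m = 2, theta0 = 0.3 on a
0.01 grid: period 1 up to kappa = 2.00, period 2 on [2.00, 3.44], period
4 on [3.45, 3.51], then 8 and 16 in single grid cells and aperiodic
dynamics from 3.54 with periodic windows (e.g. a 6-cycle near 3.73).
The aperiodic label is deliberately agnostic: the classifier reports
"no period <= 64 at tolerance 1e-6" rather than asserting chaos, since
a finite orbit cannot certify a positive Lyapunov exponent and real
biochemical oscillators are argued not to reach chaos at all.

## The coupled lattice

`diffusive_step` implements the standard nearest-neighbour coupling on a
ring (open boundaries replace the missing neighbour with the site itself,
i.e. zero flux). With epsilon = 0 it reduces exactly, elementwise, to the
single map — a tested identity.

`threshold_step` implements the adaptive transfer algorithm in three
phase-synchronous sweeps: (1) every site takes a map step; (2) excesses
delta(i) = max(x(i) - x*, 0) are computed; (3) each excess is added to
the site's rightward neighbour (the symmetry-breaking direction is fixed
for the whole run; periodic ring by default, with an open option that
discards the last site's excess). Synchrony makes the update independent
of site ordering and exactly equivariant under ring rotation.

Two transfer variants are provided because the update rule is ambiguous
about the sender:

* **literal** — the receiver gains delta(i) and the sender keeps its
  value, exactly as the update rule reads. The lattice sum is then
  non-decreasing through the transfer phase, and any site persistently
  above threshold compounds: its neighbour's excess feeds the next site,
  and values grow without bound. This variant reproduces the blow-up at
  x* = 0.15, kappa = 1.0 (N = 64 diverges within ~25 steps) and more
  generally diverges wherever transfers stay active.
* **conservative** — the sender is additionally reset to x*, so the
  transfer phase conserves the lattice sum exactly (tested at every
  step). This is the physically sensible reading of "excess is passed
  on" and the default for single runs.

The phase diagram over (x*, kappa) defaults to the **literal** variant:
it is the printed algorithm, and its divergent cells are what produces
the "undefined" regions of the diagram alongside fixed-point, n-cycle
and aperiodic regions. The two readings genuinely disagree about
individual cells: under the literal rule, a cell like (x* = 0.5,
kappa = 2.6) diverges; under the conservative rule with a homogeneous
initial state, send and receive cancel on the ring and that cell
reproduces the single-map 2-cycle — the "2-cycles at threshold 0.5"
regime. Both behaviors are asserted in the tests. With random initial
states the conservative variant at that cell shows an aperiodic
three-value pattern (the two 2-cycle branches plus pauses at x*), a
reminder that the diagram is qualitative: its exact cell labels depend
on initial conditions and classification tolerance.

Phase-diagram defaults: N = 64 sites, x* in [0.05, 1.0] step 0.05,
kappa in [0.5, 4.5] step 0.05, 10,000 iterations, shared seeded uniform
[0, 1) initial state across cells, classification on the trailing 128
states (2 x max period) per cell. All cells are iterated as one batch,
so the default 20 x 81 grid completes in about a minute on one core.
Divergent cells are frozen at detection to keep the batch finite.
Where x* exceeds the orbit range (the x* = 1.0 row: the map sends (0,1)
into (0,1) for all scanned kappa), transfers never trigger and the row
reproduces the single-map cascade — the measured oscillatory onset
there sits exactly at the kappa = 2 boundary; with transfers active the
onset (of any non-fixed-point label) can only move earlier.

## The convection analog

The fluid-layer formulas are implemented verbatim: turnover time
tau_RB = mu / (rho g alpha_T d deltaT) and Rayleigh number
R = rho g alpha_T d^3 deltaT / (mu D_T) with the sustained-convection
flag R >= R_RB. They are degree -1 and degree +3 homogeneous in deltaT
and d respectively (property-tested).

The cellular analog replaces gravity by a specific energy density Phi
(erg g^-1 = cm^2 s^-2) and the thermal gradient by a concentration
gradient: tau = nu / (Phi alpha deltaC). Two unit pitfalls are handled
explicitly rather than silently:

* Literature "energy rate density" values are quoted per second
  (erg g^-1 s^-1). Inserting them makes tau come out in units of T^2,
  not T; `dimension_check` performs the (L, M, T) exponent bookkeeping
  and fails for that reading. The formula needs the time-integrated
  specific energy density.
* nu is kinematic (cm^2 s^-1). The cytoplasm is taken ~1000x more
  viscous than water: 10 P dynamic viscosity at unit density gives the
  default nu = 10 cm^2 s^-1.
* alpha (default 1e-4) must carry units inverse to the concentration
  used, so alpha * deltaC is dimensionless; this is enforced by
  documentation and `dimension_check` only.

Since the specific metabolic rate falls with concentration with scaling
exponents between -0.5 and 0, Phi depends on the gradient through the
simplest law consistent with that: Phi(deltaC) = Phi0 (deltaC/c_ref)^beta
with beta clamped to [-0.5, 0]. The resulting tau is strictly
decreasing in deltaC for every admissible beta.

`fit_tau` estimates (Phi0, beta) with alpha, nu held fixed — only the
product nu/(Phi0 alpha) is identifiable otherwise — by weighted linear
least squares in log space (the model is exactly linear there:
log tau = intercept - (1 + beta) log deltaC). Relative error bars make
the noise additive in log space, which is why the fit lives there.
A slope outside the clamp returns the boundary beta with a flag, and the
intercept is re-estimated at the clamped slope.

## Reaction kinetics

The enzyme scheme E + S <-> ES -> E + P is integrated as full mass
action (LSODA, rtol 1e-10, atol 1e-12); the two linear conservation laws
E + ES and S + ES + P drift by < 1e-8 relative over the default run and
serve as the integration check. With e_total/s0 <= 1e-2 the
instantaneous velocity kcat*[ES] matches the Michaelis-Menten closed
form vmax S/(Km + S), Km = (kr + kcat)/kf, within 2% after the initial
binding transient — the quasi-steady-state cross-validation.

The coupled glucose/pH feedback system dx/dt = ax - bxy,
dy/dt = -cy + dxy (Lotka-Volterra form; defaults a = 0.3, b = 0.4,
c = 0.2, d = 0.2) has the unique positive equilibrium (c/d, a/b) =
(1.0, 0.75) and the first integral

    V(x, y) = d x - c ln x + b y - a ln y,

whose level sets are the closed orbits; V is minimised at the
equilibrium. The integrator is a hand-written fixed-step classical RK4:
fixed step makes trajectories bit-for-bit reproducible and makes the
drift of V a clean error metric — halving dt cuts the drift ~16x
(measured 15.999), the signature of a 4th-order scheme. Default dt =
1e-3, t_end = 200 (several cycles); the initial condition (0.5, 0.5)
is a display choice, not a modelling claim. Orbits leaving the positive
quadrant (possible only when dt is too coarse for the parameters) raise
with advice to reduce dt rather than returning garbage. Stoichiometric
constants (2 NADH, 4 ADP-level events per glucose) are exposed as
documented constants only.

## Synthetic dose-response tables

`generate_period_data` emulates a dose table of oscillation period
against injected sugar concentration: the time-constant curve evaluated
on a dose grid, times multiplicative log-normal noise
exp(N(0, noise_rel)) — the right noise model for ~10% *relative* error
bars, and the generator's sigma column records exactly that level.
Defaults: 20 log-spaced doses over 5-200 concentration units, true
Phi0 = 250 erg g^-1 (single-cell scale), beta = -0.25 (mid-range of the
admissible scaling exponents), noise_rel = 0.10, seed 0; identical spec
and seed give identical tables byte-for-byte.

What the generator does *not* emulate: real dose tables have few,
hand-picked doses, heteroscedastic errors, possible systematic drift of
the extract over the experiment, and a period floor at high dose where
the oscillation washes out. Parameter-recovery results on this generator
therefore show the estimator is correct under its own noise model, not
that the power law is the true biology.

## Known limitations

* Orbit classification is tolerance- and window-based; marginal cells
  near a bifurcation (multiplier magnitude ~1, algebraically slow
  convergence) can classify either side of the boundary at the 1e-6
  tolerance. The grid-cell slack in all boundary assertions covers this.
* The lattice phase diagram is qualitative by construction; initial
  conditions, lattice size and tolerance all move individual cell
  labels. Only its region structure and the analytic onset boundary are
  claimed.
* The convection analogy is a timescale argument, not a fluid
  simulation; no Boussinesq/Navier-Stokes solver is included, and the
  Rayleigh formulas apply to the fluid layer, not the cell.
* Arnold-tongue/winding-number analysis and Lyapunov exponents are out
  of scope (the map has no rotation term and chaos is not asserted).
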