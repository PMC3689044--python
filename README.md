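# glycodyn

Simulators for the nonlinear dynamics of glycolytic oscillations — the
periodic rise and fall of glycolytic intermediates (NADH, ATP, pH) seen in
yeast extracts and living cells when glucose is supplied in excess. The
package is aimed at systems-biology and biophysics researchers who want a
small, fully reproducible toolkit for exploring how a nutrient gradient can
drive a cell's metabolism through a cascade of dynamical transitions, the
chain of events proposed to initiate the Warburg effect (persistent
glycolysis terminating in lactate even under ample oxygen).

Four model layers, each a library module with a matching CLI subcommand:

1. **Sine-circle map** (`glycodyn.circle_map`) — a single glycolytic
   oscillator as the iterated map

   θ<sub>t+1</sub> = θ<sub>t</sub> + (κ/2π)·sin(mπθ<sub>t</sub>),  m = 2 by default,

   where κ plays the role of the glucose drive. The nontrivial fixed point
   loses stability at κ = 4/m (κ = 2 for m = 2), launching a
   period-doubling cascade: fixed point → 2-cycle → 4-cycle → aperiodic.

2. **Coupled map lattice** (`glycodyn.lattice`) — a ring of these maps,
   coupled either diffusively,
   x′(i) = (1−ε)f(x(i)) + (ε/2)[f(x(i+1)) + f(x(i−1))],
   or by sandpile-like *threshold transfer*: after each map sweep, any
   site above a threshold x\* sends its excess δ(i) = x(i) − x\* to one
   fixed neighbour. The (x\*, κ) phase diagram shows fixed-point, n-cycle,
   and "undefined" (divergent or aperiodic) regions; the literal transfer
   rule can blow up (e.g. at x\* = 0.15, κ = 1.0).

3. **Convection analog** (`glycodyn.convection`) — the characteristic
   oscillation time of a cell under a nutrient gradient ΔC, by analogy
   with the turnover time of Rayleigh–Bénard convection rolls
   (τ_RB = μ/(ρ g α_T d ΔT), onset at Rayleigh number
   R = ρ g α_T d³ΔT/(μ D_T) ≥ R_c):

   τ = ν / (Φ(ΔC) · α · ΔC),  Φ(ΔC) = Φ₀ (ΔC/c_ref)^β,  β ∈ [−0.5, 0],

   with ν the cytoplasmic kinematic viscosity, Φ the specific energy
   density of metabolism and α·ΔC dimensionless. Includes dimensional
   checking and weighted log-space fitting of (Φ₀, β) to
   period-versus-concentration tables.

4. **Reaction kinetics** (`glycodyn.kinetics`) — mass-action integration
   of E + S ⇌ ES → E + P with its Michaelis–Menten reduction, and the
   minimal phase-lagged glucose/pH feedback system
   dx/dt = ax − bxy, dy/dt = −cy + dxy, validated through its first
   integral V = dx − c·ln x + by − a·ln y.

A seeded synthetic-data generator (`glycodyn.datasets`) emulates
period-versus-concentration dose tables with ~10% relative error bars.

## Worked example

```python
>>> import numpy as np, glycodyn as g
>>> g.stability_boundary(2)            # period-doubling onset, kappa = 4/m
2.0
>>> orbit = g.iterate(g.CircleMapParams(kappa=2.5, theta0=0.3))
>>> g.classify_attractor(orbit)
AttractorLabel(kind='cycle', period=2, tolerance=1e-06)
>>> np.round(orbit.states[-4:], 6)     # the two alternating branch values
array([0.680021, 0.319979, 0.680021, 0.319979])
>>> p = g.CellParams(nu=10.0, phi0=250.0, alpha=1e-4, beta=0.0)
>>> g.cell_time_constant(p, 10.0)      # seconds per oscillation at dC = 10
40.0
>>> spec = g.SyntheticSpec(phi0=250.0, beta=-0.25, noise_rel=0.10, seed=0)
>>> fit = g.fit_tau(g.generate_period_data(spec), alpha_fixed=spec.alpha,
...                 nu_fixed=spec.nu, c_ref=spec.c_ref)
>>> round(fit.phi0, 2), round(fit.beta, 4)
(254.43, -0.2357)
```

Just past the boundary κ = 2 the oscillator alternates between two
branches (a 2-cycle, the doubled glycolytic oscillation); the cellular
time constant says a gradient of 10 concentration units yields a 40 s
oscillation at the default viscosity and metabolic energy density; and
fitting 20 noisy synthetic dose-response points recovers the generating
Φ₀ = 250 erg g⁻¹ and β = −0.25 to within a few percent.

The same computations are available from the shell, each writing a CSV
plus a JSON sidecar (parameters, seed, version) so every artifact can be
regenerated exactly:

```bash
glycodyn bifurcation --kappa-min 0.5 --kappa-max 4.5 --kappa-step 0.01 --out bif.csv
glycodyn phase-diagram --size 64 --variant literal --out phase.csv
glycodyn synth-data --seed 0 --out periods.csv
glycodyn tau-fit --data periods.csv --out fit.csv
glycodyn ode-run --a 0.3 --b 0.4 --c 0.2 --d 0.2 --out traj.csv
```

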