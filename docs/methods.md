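# Methods

## Model

`clusterbind` simulates monovalent ligands binding reversibly to monovalent,
immobile receptors on a 1D membrane bounding a 2D medium. Ligands are point
particles with over-damped Brownian motion in the Euler discretization

    x(t+dt) = x(t) + sqrt(2 D dt) Z1,
    y(t+dt) = y(t) + sqrt(2 D dt) Z2,

Z1, Z2 iid standard normal. The x axis is periodic over the membrane length
L; y reflects at the membrane (y = 0) and at the top wall (y = H). Each
receptor carries a square *affinity zone* of side b above its membrane
position. A free ligand inside the zone of a free receptor binds with
probability p1 per step; a complex dissociates with probability p-1 per
step; bound ligands do not move. On dissociation the ligand restarts at the
center of the top edge of the zone it left, so the next step is an unbiased
choice between returning into the zone and moving away; the `random_bulk`
reinjection mode instead relocates it uniformly in the box, which
deliberately removes rebinding.

Each step applies, in order: unbinding of every complex, diffusion of every
free ligand (including those released this step), then one binding sweep.
In a sweep each candidate ligand gets at most one Bernoulli(p1) trial, a
receptor accepts at most one ligand, competing candidates are processed in
uniformly random order, and a ligand covered by several free zones picks its
target uniformly. A dissociated receptor is immediately eligible for
rebinding in the same step. For layouts whose zones never overlap the sweep
is sampled in closed form (a receptor with k candidates binds with
probability 1 - (1 - p1)^k and the winner is uniform by symmetry), which is
exactly equivalent in law to the sequential sweep.

Matching per-step dissociation flux p-1·c against the well-mixed encounter
rate p1·l·(S_r/S_t) per free receptor gives the dissociation constant in
ligand-count units,

    kappa = (p-1 / p1) * (S_t / S_r),

which makes the simulation directly comparable to the classical equilibrium
c* = l*/(1 + l*) with l* = l/kappa and c* = c/r0.

## Cluster equilibrium theory

A cluster of n receptors whose zones coincide behaves as one macromolecule
with n equivalent sites. With identical microscopic on-rates (k_i = k1) and
release proportional to occupancy (k_-i = i k_-1, i.e. kappa_i = i kappa),
detailed balance over the occupancy ladder C_{i-1} <-> C_i gives cluster
populations c_i proportional to l*^i / i!, hence the site occupancy

    c*(l*, n) = sum_{i=1..n} i a_i / (n sum_{i=0..n} a_i),  a_i = l*^i / i!.

Its corollaries are the quantities the package measures: slope at the
origin 1/n, saturation at 1, and EC50* -> n/2 for large n (the exact EC50 is
the unique root of c* = 1/2; at n = 2 it is sqrt(2)). Terms are accumulated
with the multiplicative recurrence a_i = a_{i-1} l*/i and renormalized by a
running scale, so the formula is stable for n up to at least 10^3 and
arbitrary doses. For closed boxes the finite ligand pool is handled by
solving c = r0 c*((l_tot - c)/kappa, n) for c (`closed_system_occupancy`);
all engine-vs-theory comparisons use this depletion-aware form.

## Geometry and the box aspect

The model pins only the area ratio S_t/S_r; how the area splits into L x H
is free, and it matters: it sets the membrane coverage fraction r0 b / L
(how much depleted membrane exists) and the escape geometry above a zone.
The package fixes the aspect by a coverage rule (L = r0 b / coverage,
H = S_t / L) with default coverage 0.12. That value is a calibration: at
the reference kinetics (p1 = p-1 = 0.1) and reference dose l* = 1 the
homogeneous control then reproduces the classical equilibrium within ~1% —
which is the defining property of the reference configuration. Shallower
boxes overshoot (excess rebinding), deeper boxes undershoot (depletion).
The calibration was fixed before any clustering experiment was evaluated
and is not revisited per experiment.

## Parameter profiles

| parameter | paper profile | desk profile |
|---|---|---|
| receptors r0 | 500 | 100 |
| space ratio S_t/S_r | 5e5 | 1e3 |
| kappa (p1 = p-1) | 5e5 ligands | 1e3 ligands |
| box (b units) | L=4167, H=120 | L=833, H=1.2 |
| dt, D | 1e-2, 1 | 1e-2, 1 |
| steps (burn-in + window) | 1000 + 1000 | 1000 + 1000 |

The desk profile keeps every dimensionless control (l*, p-1/p1, coverage,
aspect rule) while shrinking the particle pool ~500x, so full dose-response
sweeps over cluster sizes {1, 2, 5, 10, 20, 50, 100} run in minutes on one
CPU. The cost is a shallow box (H = 1.2 b): lateral diffusion near the
membrane is quasi-1D and hence recurrent, which inflates rebinding when
dissociation is frequent. In practice the homogeneous control stays within
~1% of theory at the calibration kinetics, but conditions with
p-1 >> p1 (kappa* = 10) show a stable +3-4% occupancy excess at high doses
that no desk-reachable aspect removes; the full-size profile does not have
this problem but is ~500x more expensive per curve. Equilibration uses 1000
burn-in steps (the reaction relaxation time is 1/p-1 = 10 steps; occupancy
plateaus well within 10^3 steps, matching the expected equilibration
scale); validation runs additionally stretch the burn-in to at least five
bound-state lifetimes (5/p-1), which matters for slow-unbinding conditions
such as kappa* = 0.1 where 1/p-1 = 1000 steps. Every run is checked by a
plateau guard that flags drift between the two halves of the averaging
window larger than 2 s.d.

## Estimators

- **Equilibrium occupancy**: mean of c(t)/r0 over the last `window` steps;
  replicate mean +- s.d. across independent seeds (default 10 replicates,
  20 for the low-dose slope grid where relative noise is largest).
- **Slope at origin**: through-origin least squares of c* on l* restricted
  to l* <= 0.05 (c*(0) = 0 holds exactly, so the intercept is fixed).
- **EC50**: Hill fit c* = l*^a / (k^a + l*^a) by unweighted nonlinear least
  squares in log-parameter space, multi-started from a 4x3 grid of
  (k, a) in {0.5, 1, 2, 5} x {0.5, 1, 2}. The Hill form is an empirical
  EC50 reader here, not a mechanistic model of clustered binding.
- **MFPT**: first entry step of non-interacting diffusers into any zone,
  uniform starts, start-inside = 0. Walkers still outside after the step
  cap (default 10^4) are censored: excluded from the fit and counted. The
  headline estimate fits an exponential pdf to the FPT histogram by least
  squares with Poisson-standardized residuals (sparse tail bins carry the
  weight they deserve, empty bins stay in); the raw sample mean is reported
  alongside. Censoring matters: in deep boxes most walkers never arrive
  within the cap, and the fitted "MFPT" then reflects the observation
  window as much as the geometry — which is why the absolute MFPT is the
  least transferable number the package produces (see Limitations).

## Randomness and reproducibility

Every experiment derives all run seeds from one root `SeedSequence` labeled
by (user seed, experiment tag), so experiments are independent and
bit-reproducible; paired designs (edge vs random reinjection) reuse the
same child sequence so both arms see identical seeds. The compiled step
loop uses a splitmix64-seeded xorshift128+ stream with Box-Muller normals;
the numpy fallback path uses PCG64. Both are deterministic given the run
seed; trajectories are reproducible within a path.

## Design choices where the model description is open

- Event order (unbind -> move -> bind) lets a just-released ligand take one
  diffusion step from the zone's top edge before its next binding chance.
- A receptor freed in a step can rebind in the same step (memoryless).
- Binding candidates are processed in a freshly randomized order each step.
- "Spreading" inside a cluster is parameterized by center-to-center spacing
  r = spacing_ratio * b with zone width fixed; spacing is the only
  observable consequence of a receptor "width".
- Partial overlap shifts neighboring zones by (1 - f) b, interpolating
  linearly between contiguous (f = 0) and fully stacked (f = 1).
- Doses are total ligand counts; at desk scale r0/kappa = 0.1, so low doses
  are measurably depleted by binding. Validation therefore compares against
  the closed-system equilibrium, and each curve records its mean free
  ligand so the approximation l_free ~ l_total is auditable.

## What the simulations do and do not emulate

The generator reproduces the study conditions: 2D medium, 1D membrane,
immobile receptors, ideal (non-interacting) ligands, equilibrium read out
from the occupancy time average. It does not emulate 3D media or spherical
cells, receptor diffusion, receptor-receptor coupling (dimerization,
transphosphorylation, allostery), ligand-ligand exclusion, or lipid-raft
biophysics. Passing tests therefore support claims about this idealized
geometry only; in particular absolute first-passage times and the exact
plateau level of the EC50 ratio depend on the box aspect, which real
membranes do not share.

## Known limitations

- The box aspect is the one free geometric parameter; absolute MFPT values
  and (weakly) the clustering plateau depend on it. The coverage-0.12
  calibration is principled but not unique.
- At desk scale the kappa* = 10 validation deviates from the well-mixed law
  by a few percent at high doses (shallow-box rebinding recurrence); the
  deviation is a property of the scaled geometry, not of the algorithm.
- The MFPT cap censors heavily in deep boxes; fitted MFPTs under heavy
  censoring are lower bounds tied to the observation window.
- The Hill fit is known to be qualitatively wrong for cluster curves
  (non-zero slope at origin); it is used only to extract EC50.
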