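# clusterbind

Particle-based Monte-Carlo simulation and equilibrium theory of ligand
binding to **clustered membrane receptors**.

Cell-surface receptors are often not spread evenly over the membrane: they
gather in clusters inside micro-domains. Classical binding equations (law of
mass action) ignore this, because they assume reactants are well mixed.
`clusterbind` asks what clustering alone — no receptor-receptor biochemistry,
just geometry — does to whole-cell dose-response curves, and answers it two
ways:

1. **Analytic theory.** For clusters of n receptors that share one binding
   region ("over-stacked": an n-site macromolecule with kappa_i = i kappa),
   the equilibrium site occupancy is

       c*(l*, n) = sum_{i=1..n} i a_i / (n sum_{i=0..n} a_i),  a_i = l*^i/i!,

   with l* = l/kappa, c* = c/r0, kappa = k-1/k1. Slope at origin 1/n;
   EC50* -> n/2 for large n (exactly sqrt(2) at n = 2).

2. **Particle simulation.** Ligands diffuse (over-damped 2D Brownian motion,
   x periodic, y reflecting) above a membrane carrying immobile receptors
   with square *affinity zones*; binding and unbinding are per-step Bernoulli
   events (p1, p-1) with kappa = (p-1/p1)(S_t/S_r). This resolves layouts the
   theory cannot: clusters of *contiguous* (touching, non-overlapping) zones,
   partial overlap, intra-cluster spreading, rebinding control experiments,
   and first-passage-time measurements.

The central result both routes agree on: **clustering lowers the apparent
affinity** — EC50 rises, the slope at origin falls — while every receptor's
microscopic affinity stays fixed. A cell could therefore tune its
sensitivity just by re-arranging receptors.

Audience: modelers of receptor-level signaling and anyone needing a small,
fast, reproducible testbed for spatially correlated binding kinetics.

## Worked example

```python
from clusterbind import ExperimentConfig, run_contiguous_sweep, ec50_exact

cfg = ExperimentConfig.desk(seed=1, replicates=5, slope_replicates=10)
result = run_contiguous_sweep(cfg, cluster_sizes=(1, 5, 20, 100))
cols = ["n", "ec50_ratio", "slope_ratio", "alpha"]
print(result.summary[cols].round(3).to_string(index=False))
```

prints (a few minutes on one CPU; identical rerun to rerun at fixed seed):

```
  n  ec50_ratio  slope_ratio  alpha
  1       1.000        1.000  1.104
  5       1.155        0.754  1.161
 20       1.350        0.682  1.195
100       1.444        0.575  1.217
```

Reading: with 100 receptors grouped into ever larger contiguous clusters —
same microscopic p1, p-1, same total receptor count — the half-occupancy
dose (`ec50_ratio`, Hill fit, normalized to the unclustered control) rises
toward its plateau, and the low-dose sensitivity (`slope_ratio`,
through-origin regression on doses below 0.05 kappa) falls toward ~0.5.
The Hill exponent `alpha` creeps up only mildly (~10-20%), which is why it
serves as an EC50 reader here rather than a cooperativity claim.

The scaled "desk" profile (r0 = 100, S_t = 10^3 S_r, kappa = 10^3 ligands)
preserves all dimensionless controls of the full-size system (r0 = 500,
S_t = 5e5 S_r); see `docs/methods.md` for the geometry calibration and what
the scaling does and does not preserve. `examples/` contains one short
script per capability (theory curves, engine validation, cluster sweep,
first passage, rebinding control).

A thin CLI wraps the experiment pipelines:

```bash
clusterbind sweep-clusters --seed 1 --out results/clusters --replicates 5
clusterbind mfpt --scale paper --seed 1 --out results/mfpt
```

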