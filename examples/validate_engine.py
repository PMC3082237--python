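"""Particle engine vs the classical binding equilibrium.

Runs the homogeneous-layout validation at the desk scale (r0 = 100,
S_t = 10^3 S_r) for the reference affinity and prints per-dose z-scores of
simulated occupancy against the closed-system equilibrium solution.
Takes ~1 minute on one CPU.
"""

from clusterbind import ExperimentConfig, run_validation_homogeneous

cfg = ExperimentConfig.desk(seed=0, replicates=5)
result = run_validation_homogeneous(cfg, kappa_stars=(1.0,))

print(result.summary.round(4).to_string(index=False))
print(
    "\nReading: c_star_sim is the replicate-mean equilibrium occupancy, "
    "c_star_theory the closed-system classical value; |z| <~ 3 at every dose "
    "means the particle system reproduces the well-mixed law at this scale."
)
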