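"""Apparent affinity vs cluster size for contiguous receptor clusters.

Simulates dose-response curves for a few cluster sizes (zones touching but
not overlapping), Hill-fits the EC50, fits the slope at origin on doses
below 0.05 kappa, and prints both normalized by the unclustered control.
Takes a few minutes on one CPU; use more replicates for smoother ratios.
"""

from clusterbind import ExperimentConfig, run_contiguous_sweep

cfg = ExperimentConfig.desk(seed=1, replicates=5, slope_replicates=10)
result = run_contiguous_sweep(cfg, cluster_sizes=(1, 5, 20, 100))

cols = ["n", "ec50_ratio", "slope_ratio", "alpha"]
print(result.summary[cols].round(3).to_string(index=False))
print(
    "\nReading: ec50_ratio > 1 and slope_ratio < 1 with growing n - the same"
    "\nreceptors, merely grouped, need more ligand for the same response."
    "\nMicroscopic affinity (p1, p-1, kappa) is identical in every row."
)
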