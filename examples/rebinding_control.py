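"""How much of the clustering effect does rebinding hide?

Compares dose-response EC50s between the standard release rule (ligand
restarts at the top edge of the zone it left) and random-bulk reinjection
(rebinding switched off), for unclustered receptors and one large cluster
size.  Several minutes on one CPU.
"""

from clusterbind import ExperimentConfig, run_reinjection

cfg = ExperimentConfig.desk(seed=2, replicates=5)
result = run_reinjection(cfg, cluster_sizes=(1, 100))

cols = ["n", "ec50_edge", "ec50_random", "mode_ratio", "cluster_ratio_random"]
print(result.summary[cols].round(3).to_string(index=False))
print(
    "\nReading: mode_ratio = EC50(random)/EC50(edge) at fixed n is the price"
    "\nof losing rebinding - it grows with n because clustered receptors"
    "\nrecapture released ligand best. cluster_ratio_random is the clustering"
    "\npenalty with rebinding off: far larger than the standard-rule penalty,"
    "\nshowing rebinding partially compensates the reduced encounter rate."
)
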