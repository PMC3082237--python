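"""Mean first passage time of a ligand into any affinity zone.

Releases non-interacting walkers uniformly in the full-size box
(r0 = 500, S_t = 5e5 S_r), records each walker's first entry step into any
zone, and fits an exponential probability density to the passage times, the
diffusion-time-scale diagnostic of the binding regime.  ~10 s on one CPU.
"""

from clusterbind import ExperimentConfig, run_mfpt

cfg = ExperimentConfig.paper(seed=0)
res = run_mfpt(cfg)

print(f"particles released:      {res['n_particles']}")
print(f"arrived within cap:      {res['n_particles'] - res['n_censored']}"
      f" (cap {res['max_steps']} steps)")
print(f"MFPT, exponential fit:   {res['mfpt_fit']:.0f} +- {res['mfpt_fit_stderr']:.0f} steps")
print(f"MFPT, raw sample mean:   {res['sample_mean']:.0f} +- {res['sample_stderr']:.0f} steps")
print(
    "\nReading: the diffusive search time (thousands of steps) dwarfs the"
    "\nreaction time 1/p-1 (tens of steps): binding is diffusion-limited, so"
    "\nreceptor geometry - not chemistry - controls the apparent affinity."
    "\nCensored walkers make the fitted value a window-dependent lower bound."
)
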