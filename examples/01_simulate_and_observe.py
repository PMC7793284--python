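"""Run killing simulations and read out what an imaging observer sees.

A quarter-volume arena (cell densities as in the full 700 µm setup) and four
replicates keep this demo under half a minute.  The printed summary gives
the fraction of infected cells killed, the per-capita killing rate (PCKR,
kills per CTL per 24 h) and the observed kill probability at the i-th CTL
contact, pooled over replicates.
"""

import numpy as np

import ctlsim as cs

config = cs.SimulationConfig(X_dim=441.0, Y_dim=441.0, Z_dim=441.0, N_T=50, N_I=62)
hypothesis = cs.HypothesisSpec("null", p=0.2, T_death=15.0)  # constant kill probability
motility = cs.default_motility_model()

n_reps = 4
died, at_least = np.zeros(6), np.zeros(6)
killed, pckr, never, contacts = [], [], [], 0
for rep in range(n_reps):
    result = cs.run_simulation(config, hypothesis, motility, rng=cs.replicate_rng(1, 0, rep))
    ro = cs.compute_readouts(result)
    died += ro.kill_prob_by_rank * ro.rank_population
    at_least += ro.rank_population
    killed.append(ro.n_dead)
    pckr.append(ro.pckr)
    never.append(ro.fraction_never_contacted)
    contacts += len(result.events)
pooled = np.divide(died, at_least, out=np.zeros(6), where=at_least > 0)

print(f"{n_reps} x {config.T_Sim:.0f} min simulated, {contacts} CTL-target contacts")
print(f"killed {np.mean(killed):.1f}/{config.N_I} infected cells per run "
      f"(PCKR {np.mean(pckr):.2f} kills per CTL per 24 h)")
print(f"never contacted: {np.mean(never):.2f} of targets")
print("observed kill probability at contact rank 1..6:", np.round(pooled, 3))
print("targets with >= i contacts:", at_least.astype(int))
print("Under this contact-history-independent rule the rank profile is flat",
      "up to sampling noise in the sparse high ranks.")
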