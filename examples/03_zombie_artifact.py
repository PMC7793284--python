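"""The zombie-contact artefact: history-independent killing looks integrative.

Contacts initiated with targets that have already decided to die ("zombie
contacts") are indistinguishable to an imaging observer.  They inflate the
contact counts of dead cells, so even a constant per-contact kill
probability produces an apparently increasing kill probability with contact
rank.  This script contrasts the observed rank profile without and with
zombie contacts (a few replicates of a quarter-volume arena; ~2 min).
"""

import numpy as np

import ctlsim as cs

config = cs.SimulationConfig(X_dim=441.0, Y_dim=441.0, Z_dim=441.0, N_T=50, N_I=62)
motility = cs.default_motility_model()
cases = {
    "zombies off (p=0.2, T_death=15)": cs.HypothesisSpec("null", p=0.2, T_death=15.0),
    "zombies on  (p=0.35, T_death=25)": cs.HypothesisSpec(
        "null", p=0.35, T_death=25.0, zombie_contacts=True
    ),
}

for label, hyp in cases.items():
    died, at_least = np.zeros(6), np.zeros(6)
    for rep in range(8):
        result = cs.run_simulation(config, hyp, motility, rng=cs.replicate_rng(7, 0, rep))
        ro = cs.compute_readouts(result)
        died += ro.kill_prob_by_rank * ro.rank_population
        at_least += ro.rank_population
    pooled = np.divide(died, at_least, out=np.zeros(6), where=at_least > 0)
    print(label)
    print("  observed kill probability at rank 1..6:", np.round(pooled, 3))
    print("  targets with >= i contacts:", at_least.astype(int))
print("With zombies the profile rises with rank although the mechanistic "
      "kill probability per contact is constant — the imaging artefact.")
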