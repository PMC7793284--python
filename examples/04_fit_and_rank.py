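"""Cost-based fitting and AIC ranking of killing hypotheses.

Generates a synthetic reference readout set under a known truth (null
hypothesis, p=0.2, T_death=15), grid-searches the kill probability against
it, and ranks competing hypothesis fits by AIC = 8·ln(C) + 2k.  The AIC
values of the published best-fit rows are reproduced exactly from their
printed mean costs.  Small arena and grid keep this demo around two minutes.
"""

import ctlsim as cs

config = cs.SimulationConfig(
    X_dim=441.0, Y_dim=441.0, Z_dim=441.0, N_T=50, N_I=62, T_Sim=120.0
)
motility = cs.default_motility_model()
truth = cs.HypothesisSpec("null", p=0.2, T_death=15.0)

reference, provenance = cs.generate_reference_readouts(truth, config, n_reps=4, seed=42)
print("reference generated under:", provenance["hypothesis"])

gs = cs.grid_search(
    truth, {"p": [0.1, 0.2, 0.4]}, config, motility, reference, n_reps=4, seed=7
)
print("\ncost surface (mean cost per grid point):")
print(gs.surface[["p", "mean_cost", "aic"]].to_string(index=False))
print(f"best kill probability: {gs.best.hypothesis.p} (truth was {truth.p})")

print("\nAIC from published mean costs (8 datasets, k = killing params + T_death):")
for name, cost, k in [
    ("infected cell contact integration", 4.35e-3, 2),
    ("damage and repair", 8.60e-3, 3),
    ("CTL contact integration (zombies)", 3.09e-3, 2),
]:
    print(f"  {name:38s} C={cost:.2e}, k={k} -> AIC {cs.aic(cost, k):.1f}")
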