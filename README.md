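# ctlsim

Agent-based simulation and model selection for cytotoxic T lymphocyte (CTL)
killing of virus-infected cells, as seen through the lens of 2-photon
intravital imaging.

## The problem

In vivo imaging of CTLs attacking virus-infected cells in lymph nodes shows
that infected cells contacted many times are disrupted more often than cells
contacted once — as if killing probability grows with the number of
contacts.  But an imaging observer cannot tell *which* contact sealed a
cell's fate: a target that has already committed to die keeps receiving
contacts ("zombie contacts") until it visibly disintegrates, inflating the
contact counts of dead cells.  Distinguishing genuine signal integration
(by the CTL, by the target, or through damage accumulation) from this
observational artefact requires a mechanistic simulation of the whole
imaging experiment.

`ctlsim` provides that simulation and the model-selection machinery around
it, for quantitative immunologists analysing cell-contact imaging data:

- a 3D off-lattice arena (700×700×700 µm, periodic in x/y) with 200 CTLs
  doing a persistent random walk (speed and turning-angle histograms,
  2-min persistence) among 250 stationary infected cells in the top 40%
  of the z-axis;
- hard-core nuclear collisions, a 14.85 µm interaction reach, log-normal
  contact durations (log-mean 2.1, log-sd 1.2), CTL monogamy and
  post-contact refractoriness;
- nine death hypotheses: constant probability *p*; contact integration by
  the target (*k*<sub>I</sub>·*C*<sub>I</sub>) or the CTL
  (*k*<sub>T</sub>·*C*<sub>T</sub>, or *k*<sub>T</sub>/*C*<sub>T</sub> for
  exhaustion); per-cell heterogeneity (Normal draws); and damage dynamics
  d*I*/d*t* = *n*<sub>CTL</sub>·*d* [− *r·I*], with death at *I* ≥ 1 and a
  removal delay *T*<sub>death</sub> after every death decision;
- the eight imaging readouts (kill probability by contact rank,
  T<sub>elimination</sub>, contact-count and contact-duration
  distributions by fate), PCKR and killed/never-contacted fractions;
- cost scoring C<sub>x</sub> = (1/n)ΣΣ(E−M)², grid search, and model
  ranking by AIC = 8·ln *C* + 2*k*.

## Worked example

```python
import ctlsim as cs

config = cs.SimulationConfig()                     # the full 700 µm setup
hyp = cs.HypothesisSpec("null", p=0.2, T_death=15.0)
motility = cs.default_motility_model()             # synthetic stand-in histograms

result = cs.run_simulation(config, hyp, motility, rng=1)
readouts = cs.compute_readouts(result)
print(readouts.n_dead, round(readouts.pckr, 2))
```

Running `python examples/03_zombie_artifact.py` (8 pooled quarter-volume
replicates per case) prints:

```
zombies off (p=0.2, T_death=15)
  observed kill probability at rank 1..6: [0.186 0.146 0.107 0.167 0.125 0.   ]
  targets with >= i contacts: [102  48  28  18   8   4]
zombies on  (p=0.35, T_death=25)
  observed kill probability at rank 1..6: [0.12  0.246 0.257 0.526 0.375 0.25 ]
  targets with >= i contacts: [117  65  35  19   8   4]
```

Both worlds kill with a *constant* per-contact probability, yet with zombie
contacts enabled the observed kill probability climbs from 0.12 at the
first contact to ~0.3–0.5 at high ranks — the artefact that confounds the
interpretation of contact-resolved imaging data.  The rank-profile decay in
the sparse high ranks of the zombie-off world is sampling noise (4 targets
reached six contacts).

The other examples cover the damage closed forms
(`t_complete = −(1/r)·ln(1 − r/d)` ≈ 39.6 min at d = 0.03/min,
r = 0.009/min, so damage-based killing cannot eliminate cells faster than
~30–40 min), direct simulation readouts, and a small grid-search /
AIC-ranking round trip.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from the installed package: the AIC values of six published
best-fit hypothesis rows from their mean costs and parameter counts, the
closed-form damage-completion time at the published damage/repair rates,
and the mean log contact duration from one million draws of the default
duration model.  The JSON maps target ids to the recomputed values.

## Layout

- `src/ctlsim/` — arena & motility, contact engine, death hypotheses,
  scheduler, observables, fitting, synthetic references, experiment runner.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameters, numerical choices and
  limitations.
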