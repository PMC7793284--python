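# Methods

## The model

`ctlsim` implements an off-lattice, agent-based model of cytotoxic T
lymphocytes (CTLs) killing stationary virus-infected cells in a tissue
volume comparable to a 2-photon imaging field in a lymph node.  The arena is
a 700×700×700 µm box (periodic in x and y, closed in z); 200 CTLs are placed
uniformly in the whole volume while 250 infected cells occupy only the top
40% of the z-axis, mirroring the imaging depth at which infected cells are
found.  Cells are spheres (CTL radius 4.8 µm, infected-cell radius 5.1 µm)
whose nuclei — half the cell radius (`C_CF = 0.5`) — exclude each other as
hard cores.  Time advances in 0.1-min ticks for 240 simulated minutes.

### Motility

CTLs perform a persistent random walk: every persistence time
(`T_pers` = 2 min) a cell draws a new speed from a binned speed distribution
and turns by an angle drawn from a binned turning-angle distribution,
applied in a uniformly random plane through the current heading.  Initial
persistence clocks are uniform in [0, T_pers) to desynchronise turning.
Movement within a tick is truncated at the first nucleus collision or z
boundary; a blocked cell forfeits the rest of that tick's displacement,
takes a uniformly random new direction and resets its persistence clock
(the collision response is a design choice — the underlying description
says only that a colliding cell resumes motion in another direction; we
keep the current speed and resample direction only).  z boundaries are
treated exactly like collisions, never as reflections.

### Contacts

A free CTL within `I_CF·(R_T+R_I)` = 14.85 µm of an eligible infected cell
initiates a contact (pseudopod reach, `I_CF` = 1.5), halts, and stays bound
for a duration drawn once per contact from a log-normal with log-mean 2.1
and log-sd 1.2 (log-minutes; median ≈ 8.2 min).  A CTL is monogamous; a
target can hold many simultaneous contacts.  When several targets are in
range the nearest wins, ties broken by lower target id.  A contact ends at
its scheduled time or when its target is removed, whichever is first; the
released CTL draws a fresh direction and speed and may not initiate a new
contact for one persistence time (refractory period).  Contact counters
(`C_T` per CTL, `C_I` per target) increment at initiation, so the current
contact counts in its own death decision.

### Death hypotheses

Nine mechanisms decide infected-cell death; each adds `T_death`, the fixed
delay between the death decision and the cell's visible disruption
(removal):

| variant | decision rule | fitted parameters |
|---|---|---|
| null | Bernoulli(p) at each contact end | p, T_death |
| infected_integration | Bernoulli(k_I·C_I) | k_I, T_death |
| ctl_integration | Bernoulli(k_T·C_T) (or k_T/C_T, exhaustion) | k_T, T_death |
| ctl_heterogeneity | per-CTL p ~ Normal(k_m, k_s), clamped to [0,1] | k_m, k_s, T_death |
| infected_heterogeneity | per-target p ~ Normal(d_m, d_s), clamped | d_m, d_s, T_death |
| constant_damage | dI/dt = n_CTL·d, death at I ≥ 1 | d, T_death |
| saturated_damage | per-contact damage stops after T_max | d, T_max, T_death |
| damage_repair | dI/dt = n_CTL·d − r·I | d, r, T_death |
| ctl_integration_damage | dI/dt = Σ k_T·C_T over contacting CTLs | k_T, T_death |

Linear probabilities are clamped to [0, 1] (the formulas exceed 1 at high
counts; the source is silent, clamping is the only probability-valued
reading).  Damage integrates by forward Euler at the simulation tick; the
single-contact closed forms `I(t) = (d/r)(1−e^{−rt})` and
`t_complete = −(1/r)ln(1−r/d)` serve as analytic oracles (Euler at dt = 0.1
matches within 0.5% over a 40-min contact).  When several contacts on one
target end in the same tick, each performs an independent Bernoulli decision
in random order, stopping once death is decided (additive, non-cooperative
multi-CTL effect).  Contacts truncated by the end of the simulation window
do not trigger death decisions — only naturally (scheduled) ending ones do.

### Zombie contacts

A dying target persists for `T_death` minutes.  With the zombie flag on,
CTLs may initiate new contacts with dying targets; these draw durations from
the same distribution, never feed death decisions, but are recorded as
ordinary contacts.  Contacts already running when the decision falls
continue in both modes; the flag governs new initiations only.  Because an
imaging observer counts zombie contacts like any others, dead cells'
contact counts are inflated and the observed kill probability rises with
contact rank even under the history-independent null rule — the central
interpretive artefact this package exists to quantify.

## Observables

All readouts are computed inside an observation window (default the full
240 min; the "unknown history" preset starts it at 60 min).  Contacts are
attributed by start time; contacts starting before the window are invisible,
contacts open at its end are truncated there; targets removed within the
window count as killed, all others as surviving.  The eight datasets used
for fitting: observed kill probability at the i-th contact (i = 1..6 for
cost), the T_elimination distribution (first contact → disruption, 10-min
bins), contact-count histograms for killed and surviving cells (unit bins),
and total-per-cell plus single-contact duration histograms split by fate
(5-min bins up to 60 min with an overflow bin).  Every histogram is
normalised by its own population; empty populations give all-zero
histograms flagged by the stored population sizes.  Summary statistics:
PCKR = kills per CTL linearly extrapolated to 24 h, fraction killed, and
fraction never contacted.

## Fitting and model selection

A parameter set is scored against reference readouts by
`C_x = (1/n) Σ_reps Σ_i (E_i − M_i)²` per dataset, the mean cost `C`
averaging the 8 datasets, and `AIC = 8·ln(C) + 2k` where k counts the
variant's killing parameters plus T_death.  The AIC form was validated by
reproducing all 18 published (cost, k) → AIC table rows to ±0.1 before
adoption; the zombie flag is model structure, not a fitted parameter.  Grid
search is exhaustive with replicate seeds derived from
(master seed, replicate index): the same replicate worlds are reused at
every grid point (common random numbers).  This choice exists because cost
*differences* between grid points, not absolute costs, decide the argmin;
sharing the arena placements and motility histories across grid points
cancels the simulation noise common to all of them, which with independent
seeds exceeds the cost gap between neighbouring grid points at modest
replicate counts.  Each grid point's cost still follows the per-dataset
squared-deviation form exactly.  Ties break toward smaller T_death, then
smaller killing parameters.  A binned two-sample KS statistic is reported
for completeness but never used for selection.

Even so, exact self-consistency recovery of (p, T_death) on a 5×5 grid at
10 replicates is not robust in the synthetic stand-in world: the rank-4..6
entries of the kill-probability-by-rank dataset rest on single-digit cell
counts per replicate, and their sampling variance dominates the cost.  The
kill probability recovers reliably; T_death only coarsely.

## Synthetic stand-ins

The measured CTL speed and turning-angle distributions exist only as
figures, so the package ships versioned synthetic stand-ins: speeds on
[0, 12] µm/min with mean exactly 4.5 µm/min (gamma-like shape — slow
tissue patrolling), turning angles on [0, π] biased to forward persistence
(mean ≈ 69°).  Reference readout sets are generated by running the
simulator under a known hypothesis and averaging replicates, with a
provenance JSON naming the truth.  What a green test establishes is
therefore *self-consistency* (the pipeline recovers what it generated and
reproduces published closed-form/selection numbers), not agreement with the
unpublished experimental curves.  Notably the stand-in world is
contact-sparse relative to the imaging experiments: a default null run
yields PCKR below the experimentally reported 2–16 range, so absolute
killing rates from the defaults should not be read as biological estimates.

## Numerical choices

- dt = 0.1 min throughout; death clocks expire on the first tick at or past
  zero, so removal lags decision + T_death by at most one tick.
- A contact initiated in a given tick starts damaging only from the next
  tick (it has existed for zero time when damage integrates), which keeps
  the 1/d lower bound on elimination times exact at tick resolution.
- Scheduled contact ends are logged at start + scheduled duration (the
  detachment time inside the tick), while the release itself happens at the
  tick boundary.
- Movement neighbourhoods are cached and rebuilt every 5 ticks with a
  travel margin of 2 × 5 × max-step, making the cache a superset of any
  exact per-tick neighbourhood; CTLs with no cached neighbour translate in
  a commuting batch, the rest advance sequentially in a fresh random
  permutation.  This is outcome-equivalent to a fully sequential sweep
  because cells farther apart than one tick's reach cannot interact within
  the tick.
- Initial placement uses bounded rejection sampling (10⁵ failed draws)
  and reports the densest constraint on failure.
- Heterogeneity draws clamp to [0, 1] without redraw.
- T_death grid values are exact constants; the ±2.5 reported alongside
  published best fits is read as the grid half-step.

## Known limitations

- No chemotaxis, target motility, or deformable shapes; volume exclusion is
  nucleus-only.
- One duration distribution serves live and zombie contacts alike.
- The synthetic motility stand-ins are placeholders; users with tracking
  data should supply their own TSV histograms.
- Self-consistency parameter recovery identifies the killing probability
  well, but T_death only coarsely at reduced replicate counts: its
  observable signature (a shift of the T_elimination histogram by a
  fraction of a bin) is small against replicate noise in the per-dead-cell
  histograms.
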