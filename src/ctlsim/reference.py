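"""Synthetic stand-in inputs and scenario presets.

The imaging study this model emulates published its CTL speed, turning-angle
and readout distributions only as figures, so this module generates
documented synthetic stand-ins: a versioned speed/turning-angle histogram
pair (the constants below are frozen — never regenerated silently), and
self-consistent reference readout sets produced by running the simulator
itself under a known hypothesis, with a provenance record stating the truth.
Parameter-recovery tests fit against these references.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .config import ContactDurationModel, SimulationConfig
from .hypotheses import HypothesisSpec
from .motility import BinnedDistribution, MotilityModel
from .observables import ReadoutSet, average_readouts, compute_readouts
from .simulation import run_simulation

__all__ = [
    "default_motility_model",
    "generate_reference_readouts",
    "scenario_presets",
    "Scenario",
    "BEST_FIT_NO_ZOMBIES",
    "BEST_FIT_ZOMBIES",
]

# Synthetic stand-in speed distribution: 1 µm/min bins on [0, 12] µm/min,
# gamma-like shape adjusted so the sampled mean is exactly 4.5 µm/min
# (a slow tissue-patrolling CTL population).
_SPEED_EDGES = np.arange(0.0, 13.0, 1.0)
_SPEED_PROBS = np.array(
    [
        0.018669272727272656, 0.122099, 0.1751, 0.17729, 0.151127, 0.116272,
        0.083572, 0.057227, 0.037792, 0.024265, 0.015233, 0.021353727272727264,
    ]
)

# Synthetic stand-in turning-angle distribution: 12 bins on [0, π], biased
# towards forward persistence (mean turn ≈ 69°).
_TURN_EDGES = np.linspace(0.0, np.pi, 13)
_TURN_PROBS = np.array(
    [
        0.037516000000000084, 0.095171, 0.138202, 0.160546, 0.160681, 0.141728,
        0.110399, 0.075088, 0.043624, 0.02128, 0.009578, 0.006187,
    ]
)


def default_motility_model() -> MotilityModel:
    """The versioned synthetic speed/turning-angle histograms."""
    return MotilityModel(
        speed_hist=BinnedDistribution(edges=_SPEED_EDGES.copy(), probabilities=_SPEED_PROBS.copy()),
        turn_hist=BinnedDistribution(edges=_TURN_EDGES.copy(), probabilities=_TURN_PROBS.copy()),
    )


def generate_reference_readouts(
    hyp: HypothesisSpec,
    config: SimulationConfig,
    n_reps: int,
    seed: int,
    out_dir: str | Path | None = None,
    motility: MotilityModel | None = None,
    duration_model: ContactDurationModel | None = None,
    max_rank: int = 6,
) -> tuple[ReadoutSet, dict]:
    """Run the simulator under a known hypothesis and average its readouts.

    Returns the replicate-averaged ReadoutSet and a provenance record naming
    the generating hypothesis, parameters and seed (so recovery tests know
    the truth); both are written to ``out_dir`` when given.
    """
    if motility is None:
        motility = default_motility_model()
    readouts = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        result = run_simulation(config, hyp, motility, duration_model, rng=rng)
        readouts.append(compute_readouts(result, max_rank=max_rank))
    reference = average_readouts(readouts)
    provenance = {
        "synthetic": True,
        "generator": "ctlsim.reference.generate_reference_readouts",
        "hypothesis": {
            "variant": hyp.variant,
            **hyp.killing_parameters,
            "T_death": hyp.T_death,
            "zombie_contacts": hyp.zombie_contacts,
        },
        "n_reps": n_reps,
        "seed": seed,
        "config": {"N_T": config.N_T, "N_I": config.N_I, "T_Sim": config.T_Sim},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        reference.to_dir(out_dir)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return reference, provenance


# Best-fit parameter sets without / with zombie contacts (ranking tables of
# the study this reproduces), keyed by variant.
BEST_FIT_NO_ZOMBIES: dict[str, HypothesisSpec] = {
    "infected_integration": HypothesisSpec("infected_integration", k_I=0.09, T_death=15),
    "ctl_integration_damage": HypothesisSpec("ctl_integration_damage", k_T=0.008, T_death=10),
    "ctl_integration": HypothesisSpec("ctl_integration", k_T=0.1, T_death=20),
    "null": HypothesisSpec("null", p=0.2, T_death=15),
    "constant_damage": HypothesisSpec("constant_damage", d=0.03, T_death=35),
    "damage_repair": HypothesisSpec("damage_repair", d=0.03, r=0.009, T_death=40),
    "saturated_damage": HypothesisSpec("saturated_damage", d=0.03, T_max=20, T_death=35),
    "ctl_heterogeneity": HypothesisSpec("ctl_heterogeneity", k_m=0.18, k_s=0.05, T_death=30),
    "infected_heterogeneity": HypothesisSpec("infected_heterogeneity", d_m=0.1, d_s=0.05, T_death=15),
}

BEST_FIT_ZOMBIES: dict[str, HypothesisSpec] = {
    "ctl_integration": HypothesisSpec("ctl_integration", k_T=0.14, T_death=35, zombie_contacts=True),
    "infected_integration": HypothesisSpec("infected_integration", k_I=0.18, T_death=35, zombie_contacts=True),
    "null": HypothesisSpec("null", p=0.35, T_death=25, zombie_contacts=True),
    "ctl_integration_damage": HypothesisSpec("ctl_integration_damage", k_T=0.014, T_death=10, zombie_contacts=True),
    "saturated_damage": HypothesisSpec("saturated_damage", d=0.06, T_max=10, T_death=15, zombie_contacts=True),
    "constant_damage": HypothesisSpec("constant_damage", d=0.03, T_death=35, zombie_contacts=True),
    "ctl_heterogeneity": HypothesisSpec("ctl_heterogeneity", k_m=0.3, k_s=0.05, T_death=30, zombie_contacts=True),
    "damage_repair": HypothesisSpec("damage_repair", d=0.03, r=0.009, T_death=5, zombie_contacts=True),
    "infected_heterogeneity": HypothesisSpec("infected_heterogeneity", d_m=0.3, d_s=0.05, T_death=15, zombie_contacts=True),
}

# The seven hypothesis/zombie combinations compatible with all readouts,
# in ascending order of cost.
_AGREEING = (
    ("ctl_integration", True),
    ("infected_integration", True),
    ("null", True),
    ("ctl_integration_damage", True),
    ("infected_integration", False),
    ("ctl_integration_damage", False),
    ("ctl_integration", False),
)

_SWEEP_COUNTS = (20, 50, 100, 150, 200, 250, 300, 350, 400)


@dataclass(frozen=True)
class Scenario:
    """A ready-to-run bundle of (config, hypothesis) pairs."""

    name: str
    runs: tuple[tuple[SimulationConfig, HypothesisSpec], ...]
    description: str
    prepare_cells: Callable | None = None


def _silence_half(ctls, targets, rng):
    """Priming setup: half the targets are antigen-silent until t = 240 min."""
    for tgt in targets[len(targets) // 2:]:
        tgt.antigen_on_time = 240.0
    return ctls, targets


def scenario_presets(name: str) -> Scenario:
    """Named experiment presets.

    ``fig2`` / ``fig3``: all nine hypotheses at their best parameters without /
    with zombie contacts.  ``fig4_vary_targets`` / ``fig4_vary_ctls``: PCKR and
    fraction-killed sweeps (N_I or N_T from 20 to 400, the other count fixed)
    for the seven agreeing hypotheses.  ``priming``: 480-min run with 500
    targets, half antigen-silent for the first 240 min.  ``unknown_history``:
    observation starts at 60 min so cells carry unseen contact history.
    """
    base = SimulationConfig()
    if name == "fig2":
        runs = tuple((base, hyp) for hyp in BEST_FIT_NO_ZOMBIES.values())
        return Scenario(name, runs, "best-fit hypotheses, zombie contacts off")
    if name == "fig3":
        runs = tuple((base, hyp) for hyp in BEST_FIT_ZOMBIES.values())
        return Scenario(name, runs, "best-fit hypotheses, zombie contacts on")
    if name == "fig4_vary_targets":
        runs = tuple(
            (base.replace(N_I=n_i), (BEST_FIT_ZOMBIES if z else BEST_FIT_NO_ZOMBIES)[v])
            for v, z in _AGREEING
            for n_i in _SWEEP_COUNTS
        )
        return Scenario(name, runs, "N_I sweep 20..400 at N_T=200")
    if name == "fig4_vary_ctls":
        runs = tuple(
            (base.replace(N_T=n_t), (BEST_FIT_ZOMBIES if z else BEST_FIT_NO_ZOMBIES)[v])
            for v, z in _AGREEING
            for n_t in _SWEEP_COUNTS
        )
        return Scenario(name, runs, "N_T sweep 20..400 at N_I=250")
    if name == "priming":
        cfg = base.replace(T_Sim=480.0, N_I=500)
        return Scenario(
            name,
            ((cfg, BEST_FIT_ZOMBIES["ctl_integration"]),),
            "500 targets, half antigen-silent until t=240 min",
            prepare_cells=_silence_half,
        )
    if name == "unknown_history":
        cfg = base.replace(obs_start=60.0)
        runs = tuple((cfg, hyp) for hyp in BEST_FIT_NO_ZOMBIES.values()) + tuple(
            (cfg, hyp) for hyp in BEST_FIT_ZOMBIES.values()
        )
        return Scenario(name, runs, "observation starts at 60 min (unseen history)")
    raise ValueError(
        f"unknown preset {name!r}; available: fig2, fig3, fig4_vary_targets, "
        "fig4_vary_ctls, priming, unknown_history"
    )
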