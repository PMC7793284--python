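"""Cost scoring, grid search, AIC model selection and KS comparison.

A parameter set is scored by simulating ``n`` replicates, computing the
eight readout datasets per replicate, and accumulating for each dataset

    C_x = (1/n) * sum over replicates of sum_i (E_x,i − M_x,i)^2,

where E is the reference readout and M the model readout.  The mean cost
C averages the 8 per-dataset costs, and hypotheses are ranked by

    AIC = N_ds * ln(C) + 2k,      N_ds = 8,

with k the number of fitted parameters (the variant's killing parameters
plus T_death).  The Kolmogorov–Smirnov statistic between binned readouts is
reported for completeness but never used for selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ContactDurationModel, SimulationConfig
from .hypotheses import HypothesisSpec
from .motility import MotilityModel
from .observables import DATASET_NAMES, ReadoutSet, compute_readouts
from .simulation import run_simulation

__all__ = [
    "CostResult",
    "GridSearchResult",
    "dataset_cost",
    "mean_cost",
    "aic",
    "readout_costs",
    "grid_search",
    "rank_hypotheses",
    "ks_compare",
]

N_DATASETS = 8


@dataclass(frozen=True)
class CostResult:
    """Cost and AIC of one hypothesis/parameter set."""

    hypothesis: HypothesisSpec
    per_dataset_cost: dict[str, float]
    mean_cost: float
    n_reps: int
    free_params: int
    aic: float


@dataclass(frozen=True)
class GridSearchResult:
    """Exhaustive cost surface plus the best-scoring point."""

    surface: pd.DataFrame
    best: CostResult


def _sse(reference: np.ndarray, model: np.ndarray) -> float:
    width = max(len(reference), len(model))
    e = np.zeros(width)
    m = np.zeros(width)
    e[: len(reference)] = reference
    m[: len(model)] = model
    return float(np.sum((e - m) ** 2))


def dataset_cost(reference: np.ndarray, replicates: list[np.ndarray]) -> float:
    """Mean over replicates of the summed squared deviation from the reference.

    Shorter vectors are zero-padded so bins align by index.
    """
    if not replicates:
        raise ValueError("at least one model replicate is required")
    reference = np.asarray(reference, dtype=float)
    return float(np.mean([_sse(reference, np.asarray(m, dtype=float)) for m in replicates]))


def mean_cost(per_dataset: np.ndarray | list[float] | dict[str, float]) -> float:
    """Arithmetic mean of the 8 per-dataset costs."""
    vals = np.asarray(
        list(per_dataset.values()) if isinstance(per_dataset, dict) else per_dataset,
        dtype=float,
    )
    if vals.size != N_DATASETS:
        raise ValueError(f"expected {N_DATASETS} per-dataset costs, got {vals.size}")
    return float(vals.mean())


def aic(C: float, k: int) -> float:
    """AIC = 8·ln(C) + 2k for a mean cost C over 8 datasets and k parameters."""
    if C <= 0:
        raise ValueError("mean cost must be strictly positive")
    if k < 1:
        raise ValueError("free parameter count must be >= 1")
    return N_DATASETS * math.log(C) + 2.0 * k


def readout_costs(reference: ReadoutSet, replicates: list[ReadoutSet]) -> dict[str, float]:
    """Per-dataset costs of replicate ReadoutSets against a reference."""
    ref = reference.datasets()
    return {
        name: dataset_cost(ref[name], [r.datasets()[name] for r in replicates])
        for name in DATASET_NAMES
    }


def _killing_param_key(hyp: HypothesisSpec) -> tuple:
    return tuple(hyp.killing_parameters[k] for k in sorted(hyp.killing_parameters))


def grid_search(
    base_hyp: HypothesisSpec,
    grid: dict[str, list],
    config: SimulationConfig,
    motility: MotilityModel,
    reference: ReadoutSet,
    n_reps: int,
    seed: int,
    duration_model: ContactDurationModel | None = None,
    max_rank: int = 6,
) -> GridSearchResult:
    """Exhaustively score every grid point against the reference readouts.

    ``grid`` maps HypothesisSpec field names (e.g. ``p``, ``T_death``) to the
    values to scan; every combination is evaluated with ``n_reps``
    replicates whose seeds derive deterministically from
    ``(seed, replicate index)`` — the same replicate worlds are reused at
    every grid point (common random numbers), so cost differences between
    grid points reflect parameter effects rather than shared simulation
    noise.  The argmin is returned with ties broken by smaller T_death,
    then smaller killing parameters.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = list(grid)
    rows = []
    results: list[CostResult] = []
    for g_idx, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        point = dict(zip(names, combo))
        hyp = base_hyp.replace(**point)
        reps = []
        for r_idx in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(r_idx,))
            )
            result = run_simulation(config, hyp, motility, duration_model, rng=rng)
            reps.append(
                compute_readouts(
                    result,
                    max_rank=max_rank,
                    t_elim_edges=reference.t_elim_edges,
                    dur_edges=reference.dur_edges,
                )
            )
        per_ds = readout_costs(reference, reps)
        C = mean_cost(per_ds)
        cost_result = CostResult(
            hypothesis=hyp,
            per_dataset_cost=per_ds,
            mean_cost=C,
            n_reps=n_reps,
            free_params=hyp.free_parameter_count,
            aic=aic(C, hyp.free_parameter_count),
        )
        results.append(cost_result)
        rows.append(
            {**point, **{f"C_{n}": c for n, c in per_ds.items()},
             "mean_cost": C, "aic": cost_result.aic}
        )
    best = min(
        results,
        key=lambda cr: (cr.mean_cost, cr.hypothesis.T_death, _killing_param_key(cr.hypothesis)),
    )
    return GridSearchResult(surface=pd.DataFrame(rows), best=best)


def rank_hypotheses(results: list[CostResult]) -> pd.DataFrame:
    """Table of hypotheses in ascending order of AIC (best model first)."""
    if not results:
        raise ValueError("no cost results to rank")
    rows = [
        {
            "hypothesis": cr.hypothesis.variant,
            "zombie_contacts": cr.hypothesis.zombie_contacts,
            "killing_parameters": ", ".join(
                f"{k}={v:g}" for k, v in cr.hypothesis.killing_parameters.items()
            ),
            "T_death": cr.hypothesis.T_death,
            "lowest_cost": cr.mean_cost,
            "aic": cr.aic,
        }
        for cr in results
    ]
    return (
        pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    )


def write_surface_tsv(result: GridSearchResult, path) -> None:
    """Cost surface as TSV: parameter columns, per-dataset costs, mean, AIC."""
    result.surface.to_csv(path, sep="\t", index=False)


def write_ranking_tsv(results: list[CostResult], path) -> None:
    """AIC ranking table as TSV (hypothesis, parameters, T_death, cost, AIC)."""
    rank_hypotheses(results).to_csv(path, sep="\t", index=False)


def ks_compare(reference_hist: np.ndarray, model_hist: np.ndarray) -> float:
    """Two-sample KS statistic on binned mass: max |ΔCDF| across bins."""
    ref = np.asarray(reference_hist, dtype=float)
    mod = np.asarray(model_hist, dtype=float)
    width = max(ref.size, mod.size)
    e = np.zeros(width)
    m = np.zeros(width)
    e[: ref.size] = ref
    m[: mod.size] = mod
    return float(np.max(np.abs(np.cumsum(e) - np.cumsum(m)))) if width else 0.0
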