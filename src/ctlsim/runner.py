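"""Configuration files and replicate experiment orchestration.

A run configuration is a YAML file with up to four sections::

    simulation:        # SimulationConfig fields; omitted fields -> defaults
      N_T: 200
      T_Sim: 240
    hypothesis:        # variant + named parameters + flags
      variant: "null"
      p: 0.2
      T_death: 15
      zombie_contacts: false
    contact_duration:  # log-normal parameters (log-minutes)
      log_mean: 2.1
      log_sd: 1.2
    motility:          # optional TSV histogram paths; omitted -> synthetic
      speed_hist: speeds.tsv
      turn_hist: angles.tsv

An empty file resolves to the full default setup (default arena, the null
hypothesis at its best fit, the default duration model, synthetic motility).
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import ContactDurationModel, SimulationConfig
from .hypotheses import HypothesisSpec
from .motility import MotilityModel, read_histogram_tsv, write_histogram_tsv
from .observables import DATASET_NAMES, ReadoutSet, average_readouts, compute_readouts, _pad
from .reference import Scenario, default_motility_model
from .simulation import events_dataframe, run_simulation

__all__ = ["parse_config", "write_config", "run_experiment", "replicate_rng"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_HYP_FIELDS = {f.name for f in dataclasses.fields(HypothesisSpec)}
_DUR_FIELDS = {f.name for f in dataclasses.fields(ContactDurationModel)}


def parse_config(path: str | Path):
    """Read a YAML run configuration.

    Returns ``(SimulationConfig, HypothesisSpec, MotilityModel,
    ContactDurationModel)``.  Unspecified fields take the package defaults;
    unknown keys and invalid values raise errors naming the offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"simulation", "hypothesis", "contact_duration", "motility"}
    if unknown:
        raise ValueError(f"{path}: unknown section(s): {', '.join(sorted(unknown))}")

    sim_raw = raw.get("simulation") or {}
    bad = set(sim_raw) - _SIM_FIELDS
    if bad:
        raise ValueError(f"{path}: unknown simulation key(s): {', '.join(sorted(bad))}")
    config = SimulationConfig(**sim_raw)

    hyp_raw = dict(raw.get("hypothesis") or {})
    if not hyp_raw:
        hyp = HypothesisSpec("null", p=0.2, T_death=15.0)
    else:
        if hyp_raw.get("variant") is None:
            hyp_raw["variant"] = "null"  # YAML reads the bare word null as None
        bad = set(hyp_raw) - _HYP_FIELDS
        if bad:
            raise ValueError(f"{path}: unknown hypothesis key(s): {', '.join(sorted(bad))}")
        hyp = HypothesisSpec(**hyp_raw)

    dur_raw = raw.get("contact_duration") or {}
    bad = set(dur_raw) - _DUR_FIELDS
    if bad:
        raise ValueError(f"{path}: unknown contact_duration key(s): {', '.join(sorted(bad))}")
    duration_model = ContactDurationModel(**dur_raw)

    mot_raw = raw.get("motility") or {}
    bad = set(mot_raw) - {"speed_hist", "turn_hist"}
    if bad:
        raise ValueError(f"{path}: unknown motility key(s): {', '.join(sorted(bad))}")
    if mot_raw:
        if not {"speed_hist", "turn_hist"} <= set(mot_raw):
            raise ValueError(f"{path}: motility needs both speed_hist and turn_hist")
        motility = MotilityModel(
            speed_hist=read_histogram_tsv(path.parent / mot_raw["speed_hist"]),
            turn_hist=read_histogram_tsv(path.parent / mot_raw["turn_hist"]),
        )
    else:
        motility = default_motility_model()
    return config, hyp, motility, duration_model


def write_config(
    path: str | Path,
    config: SimulationConfig,
    hyp: HypothesisSpec,
    duration_model: ContactDurationModel | None = None,
    motility: MotilityModel | None = None,
) -> None:
    """Write a YAML run configuration (inverse of :func:`parse_config`).

    A non-default motility model is written as TSV histograms next to the
    config file and referenced by relative path.
    """
    path = Path(path)
    doc = {
        "simulation": dataclasses.asdict(config),
        "hypothesis": {
            k: v for k, v in dataclasses.asdict(hyp).items() if v is not None
        },
    }
    if duration_model is not None:
        doc["contact_duration"] = dataclasses.asdict(duration_model)
    if motility is not None:
        write_histogram_tsv(motility.speed_hist, path.parent / "speed_hist.tsv")
        write_histogram_tsv(motility.turn_hist, path.parent / "turn_hist.tsv")
        doc["motility"] = {"speed_hist": "speed_hist.tsv", "turn_hist": "turn_hist.tsv"}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def replicate_rng(master_seed: int, config_index: int, rep_index: int) -> np.random.Generator:
    """Deterministically independent RNG for one replicate of one config."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(config_index, rep_index))
    )


def _std_readouts(readouts: list[ReadoutSet]) -> ReadoutSet:
    """Element-wise SD across replicates (zero for a single replicate)."""
    first = readouts[0]
    kwargs = {
        name: _pad([getattr(r, name) for r in readouts]).std(axis=0)
        for name in DATASET_NAMES
    }
    return ReadoutSet(
        rank_population=_pad([r.rank_population for r in readouts]).std(axis=0),
        t_elim_edges=first.t_elim_edges,
        dur_edges=first.dur_edges,
        pckr=float(np.std([r.pckr for r in readouts])),
        fraction_killed=float(np.std([r.fraction_killed for r in readouts])),
        fraction_never_contacted=float(np.std([r.fraction_never_contacted for r in readouts])),
        n_dead=0,
        n_alive=0,
        **kwargs,
    )


def run_experiment(
    runs,
    n_reps: int,
    seed: int,
    out_dir: str | Path,
    motility: MotilityModel | None = None,
    duration_model: ContactDurationModel | None = None,
    write_event_logs: bool = False,
) -> dict:
    """Run each (config, hypothesis) pair ``n_reps`` times and write outputs.

    ``runs`` is a :class:`~ctlsim.reference.Scenario` or an iterable of
    ``(SimulationConfig, HypothesisSpec)`` pairs.  Per run the mean and SD
    ReadoutSets, a summary JSON (PCKR, killed/never-contacted fractions) and
    optionally per-replicate event-log CSVs are written; a manifest records
    the software version, master seed and wall time.  Replicate seeds derive
    from ``(seed, config index, replicate index)``, so identical inputs give
    byte-identical outputs.
    """
    prepare_cells = None
    if isinstance(runs, Scenario):
        prepare_cells = runs.prepare_cells
        runs = runs.runs
    runs = list(runs)
    if motility is None:
        motility = default_motility_model()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = _time.monotonic()
    summaries = []
    for ci, (config, hyp) in enumerate(runs):
        run_dir = out_dir / f"run_{ci:03d}"
        readouts = []
        for ri in range(n_reps):
            rng = replicate_rng(seed, ci, ri)
            result = run_simulation(
                config, hyp, motility, duration_model, rng=rng,
                prepare_cells=prepare_cells,
            )
            readouts.append(compute_readouts(result))
            if write_event_logs:
                run_dir.mkdir(parents=True, exist_ok=True)
                events_dataframe(result).to_csv(run_dir / f"events_rep{ri:02d}.csv", index=False)
        mean = average_readouts(readouts)
        sd = _std_readouts(readouts)
        mean.to_dir(run_dir / "readouts_mean")
        sd.to_dir(run_dir / "readouts_sd")
        summary = {
            "run": ci,
            "variant": hyp.variant,
            "zombie_contacts": hyp.zombie_contacts,
            "T_death": hyp.T_death,
            "killing_parameters": hyp.killing_parameters,
            "N_T": config.N_T,
            "N_I": config.N_I,
            "pckr": mean.pckr,
            "pckr_sd": sd.pckr,
            "fraction_killed": mean.fraction_killed,
            "fraction_killed_sd": sd.fraction_killed,
            "fraction_never_contacted": mean.fraction_never_contacted,
        }
        (run_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        summaries.append(summary)
    manifest = {
        "package": "ctlsim",
        "version": __version__,
        "seed": seed,
        "n_reps": n_reps,
        "n_runs": len(runs),
        "wall_time_s": round(_time.monotonic() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "summary.json").write_text(json.dumps(summaries, indent=1))
    return {"manifest": manifest, "runs": summaries}
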