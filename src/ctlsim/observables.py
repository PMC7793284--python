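"""The eight imaging-style readouts plus killing-efficiency summaries.

Everything here mimics what a 2-photon observer tracking target cells would
measure inside an observation window ``[obs_start, obs_end]``: contacts are
counted by their start time, a target counts as killed only if its disruption
(removal) falls inside the window, and contacts still open at the window end
are truncated there.  Zombie contacts are observed like any other contact —
the observer cannot tell that the fate decision has already been taken, which
is precisely the artefact the simulator exists to expose.

Readout datasets (cost order):

1. observed probability of killing at the i-th interaction,
2. distribution of T_elimination (first contact → disruption) for killed cells,
3./4. distribution of the number of CTL contacts for killed / surviving cells,
5./6. distribution of total contact time per killed / surviving cell,
7./8. distribution of single contact durations for killed / surviving cells.

Summaries: PCKR (infected cells killed per CTL per 24 h), fraction of killed
cells, and fraction of cells never contacted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .simulation import SimulationResult

__all__ = [
    "TargetObservation",
    "Observation",
    "ReadoutSet",
    "observe",
    "compute_readouts",
    "average_readouts",
    "kill_probability_by_rank",
    "elimination_times",
    "contact_count_distributions",
    "contact_duration_distributions",
    "pckr",
    "fraction_killed",
    "fraction_never_contacted",
]

DATASET_NAMES = (
    "kill_prob_by_rank",
    "t_elim",
    "n_contacts_dead",
    "n_contacts_alive",
    "total_dur_dead",
    "total_dur_alive",
    "single_dur_dead",
    "single_dur_alive",
)


def default_t_elim_edges(t_sim: float = 240.0) -> np.ndarray:
    """10-minute bins on [0, T_Sim]."""
    return np.arange(0.0, t_sim + 10.0, 10.0)


def default_duration_edges() -> np.ndarray:
    """5-minute bins on [0, 60) with an open-ended overflow bin."""
    return np.append(np.arange(0.0, 65.0, 5.0), np.inf)


@dataclass
class TargetObservation:
    """What the observer recorded for one target cell."""

    target_id: int
    dead: bool
    contact_starts: np.ndarray
    contact_durations: np.ndarray
    first_contact_time: float | None
    removal_time: float | None

    @property
    def n_contacts(self) -> int:
        return len(self.contact_starts)


@dataclass
class Observation:
    """All per-target observations for one simulation and window."""

    targets: list[TargetObservation]
    n_ctls: int
    window: tuple[float, float]

    @property
    def n_observed(self) -> int:
        return len(self.targets)

    @property
    def window_length(self) -> float:
        return self.window[1] - self.window[0]


def observe(
    result: SimulationResult,
    obs_start: float | None = None,
    obs_end: float | None = None,
) -> Observation:
    """Restrict a simulation to the observation window.

    Contacts starting before ``obs_start`` are discarded (the observer never
    saw them — the "unknown history" convention), durations of contacts open
    at ``obs_end`` are truncated there, and targets removed at or before
    ``obs_start`` are excluded entirely.  Cells dying inside the window whose
    contacts all predate it count as zero-contact deaths.
    """
    cfg = result.config
    start = cfg.obs_start if obs_start is None else obs_start
    end = cfg.observation_end if obs_end is None else obs_end
    per_target: dict[int, list[tuple[float, float]]] = {}
    for ev in result.events:
        if ev.start_time < start or ev.start_time >= end:
            continue
        ev_end = end if ev.end_time is None else min(ev.end_time, end)
        per_target.setdefault(ev.target_id, []).append(
            (ev.start_time, max(0.0, ev_end - ev.start_time))
        )
    observed: list[TargetObservation] = []
    for tgt in result.targets:
        if tgt.removal_time is not None and tgt.removal_time <= start:
            continue  # disappeared before the window opened
        dead = tgt.removal_time is not None and start < tgt.removal_time <= end
        contacts = sorted(per_target.get(tgt.id, []))
        starts = np.array([c[0] for c in contacts])
        durs = np.array([c[1] for c in contacts])
        first = float(starts[0]) if starts.size else None
        observed.append(
            TargetObservation(
                target_id=tgt.id,
                dead=dead,
                contact_starts=starts,
                contact_durations=durs,
                first_contact_time=first,
                removal_time=tgt.removal_time if dead else None,
            )
        )
    return Observation(targets=observed, n_ctls=len(result.ctls), window=(start, end))


def kill_probability_by_rank(obs: Observation, max_rank: int = 6):
    """Observed probability of dying at exactly the i-th interaction.

    Entry i (1-based) is the number of killed targets whose total observed
    contact count equals i, divided by the number of targets with at least i
    contacts; 0/0 is reported as 0, with the denominator returned alongside.
    """
    counts = np.array([t.n_contacts for t in obs.targets], dtype=int)
    dead = np.array([t.dead for t in obs.targets], dtype=bool)
    probs = np.zeros(max_rank)
    at_least = np.zeros(max_rank, dtype=int)
    for i in range(1, max_rank + 1):
        denom = int(np.sum(counts >= i))
        at_least[i - 1] = denom
        if denom:
            probs[i - 1] = np.sum(dead & (counts == i)) / denom
    return probs, at_least


def _norm_hist(values: np.ndarray, edges: np.ndarray, denom: int) -> np.ndarray:
    hist, _ = np.histogram(values, bins=edges)
    return hist / denom if denom else hist.astype(float)


def elimination_times(obs: Observation, edges: np.ndarray) -> np.ndarray:
    """Normalised histogram of removal − first-contact times for killed cells."""
    vals = [
        t.removal_time - t.first_contact_time
        for t in obs.targets
        if t.dead and t.first_contact_time is not None
    ]
    n_dead = sum(t.dead for t in obs.targets)
    return _norm_hist(np.array(vals), edges, n_dead)


def contact_count_distributions(obs: Observation):
    """Unit-bin histograms of contact counts for killed and surviving cells.

    Each histogram is normalised by its own population; the surviving-cell
    histogram includes zero-contact cells, and so does the killed-cell one
    (cells contacted only before the window count as zero-contact deaths).
    """
    dead_counts = [t.n_contacts for t in obs.targets if t.dead]
    alive_counts = [t.n_contacts for t in obs.targets if not t.dead]
    size = max(dead_counts + alive_counts, default=0) + 1
    dead_hist = np.bincount(dead_counts, minlength=size).astype(float)
    alive_hist = np.bincount(alive_counts, minlength=size).astype(float)
    if dead_counts:
        dead_hist /= len(dead_counts)
    if alive_counts:
        alive_hist /= len(alive_counts)
    return dead_hist, alive_hist


def contact_duration_distributions(obs: Observation, edges: np.ndarray):
    """Total-per-cell and single-contact duration histograms, split by fate.

    Totals sum all of a cell's contact durations (simultaneous contacts add
    up) and are normalised per population; singles pool every individual
    contact and are normalised by the contact count of that population.
    """
    out = {}
    for fate, dead in (("dead", True), ("alive", False)):
        cells = [t for t in obs.targets if t.dead == dead]
        # zero-contact cells contribute a total of 0 min (first bin)
        totals = np.array([t.contact_durations.sum() for t in cells])
        singles = np.concatenate(
            [t.contact_durations for t in cells if t.n_contacts]
            or [np.empty(0)]
        )
        out[f"total_{fate}"] = _norm_hist(totals, edges, len(cells))
        out[f"single_{fate}"] = _norm_hist(singles, edges, singles.size)
    return (
        out["total_dead"],
        out["total_alive"],
        out["single_dead"],
        out["single_alive"],
    )


def pckr(obs: Observation) -> float:
    """Infected cells killed per CTL, linearly extrapolated to 24 hours."""
    if obs.n_ctls == 0:
        raise ValueError("PCKR undefined with zero CTLs")
    if obs.window_length <= 0:
        raise ValueError("observation length must be positive")
    n_killed = sum(t.dead for t in obs.targets)
    return n_killed / obs.n_ctls * (1440.0 / obs.window_length)


def fraction_killed(obs: Observation) -> float:
    """Killed targets over all observed targets (in [0, 1])."""
    if not obs.targets:
        return 0.0
    return sum(t.dead for t in obs.targets) / len(obs.targets)


def fraction_never_contacted(obs: Observation) -> float:
    """Targets with zero observed CTL contacts, over all observed targets."""
    if not obs.targets:
        return 1.0
    return sum(t.n_contacts == 0 for t in obs.targets) / len(obs.targets)


@dataclass
class ReadoutSet:
    """The eight normalised readout datasets plus summary statistics."""

    kill_prob_by_rank: np.ndarray
    rank_population: np.ndarray
    t_elim: np.ndarray
    n_contacts_dead: np.ndarray
    n_contacts_alive: np.ndarray
    total_dur_dead: np.ndarray
    total_dur_alive: np.ndarray
    single_dur_dead: np.ndarray
    single_dur_alive: np.ndarray
    t_elim_edges: np.ndarray
    dur_edges: np.ndarray
    pckr: float
    fraction_killed: float
    fraction_never_contacted: float
    n_dead: int
    n_alive: int

    def datasets(self) -> dict[str, np.ndarray]:
        """The eight vectors entering the cost, keyed by dataset name."""
        return {name: getattr(self, name) for name in DATASET_NAMES}

    def to_dir(self, path: str | Path) -> None:
        """Write one TSV per dataset plus a JSON summary."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, vec in self.datasets().items():
            if name == "kill_prob_by_rank":
                lefts = np.arange(1, len(vec) + 1, dtype=float)
                rights = lefts + 1
            elif name == "t_elim":
                lefts, rights = self.t_elim_edges[:-1], self.t_elim_edges[1:]
            elif name.startswith("n_contacts"):
                lefts = np.arange(len(vec), dtype=float)
                rights = lefts + 1
            else:
                lefts, rights = self.dur_edges[:-1], self.dur_edges[1:]
            lines = ["bin_left\tbin_right\tvalue"]
            for l, r, v in zip(lefts[: len(vec)], rights[: len(vec)], vec):
                lines.append(f"{float(l)!r}\t{float(r)!r}\t{float(v)!r}")
            (path / f"{name}.tsv").write_text("\n".join(lines) + "\n")
        summary = {
            "pckr": self.pckr,
            "fraction_killed": self.fraction_killed,
            "fraction_never_contacted": self.fraction_never_contacted,
            "n_dead": self.n_dead,
            "n_alive": self.n_alive,
            "rank_population": [int(x) for x in self.rank_population],
        }
        (path / "summary.json").write_text(json.dumps(summary, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ReadoutSet":
        path = Path(path)
        data = {}
        edges = {}
        for name in DATASET_NAMES:
            rows = [
                ln.split("\t")
                for ln in (path / f"{name}.tsv").read_text().splitlines()[1:]
                if ln.strip()
            ]
            data[name] = np.array([float(r[2]) for r in rows])
            if rows:
                edges[name] = np.append(
                    [float(r[0]) for r in rows], float(rows[-1][1])
                )
        summary = json.loads((path / "summary.json").read_text())
        return cls(
            kill_prob_by_rank=data["kill_prob_by_rank"],
            rank_population=np.array(summary["rank_population"]),
            t_elim=data["t_elim"],
            n_contacts_dead=data["n_contacts_dead"],
            n_contacts_alive=data["n_contacts_alive"],
            total_dur_dead=data["total_dur_dead"],
            total_dur_alive=data["total_dur_alive"],
            single_dur_dead=data["single_dur_dead"],
            single_dur_alive=data["single_dur_alive"],
            t_elim_edges=edges["t_elim"],
            dur_edges=edges["total_dur_dead"],
            pckr=summary["pckr"],
            fraction_killed=summary["fraction_killed"],
            fraction_never_contacted=summary["fraction_never_contacted"],
            n_dead=summary["n_dead"],
            n_alive=summary["n_alive"],
        )


def compute_readouts(
    result: SimulationResult,
    obs_start: float | None = None,
    obs_end: float | None = None,
    max_rank: int = 6,
    t_elim_edges: np.ndarray | None = None,
    dur_edges: np.ndarray | None = None,
) -> ReadoutSet:
    """Compute the full ReadoutSet from one simulation."""
    obs = observe(result, obs_start, obs_end)
    if t_elim_edges is None:
        t_elim_edges = default_t_elim_edges(result.config.T_Sim)
    if dur_edges is None:
        dur_edges = default_duration_edges()
    probs, at_least = kill_probability_by_rank(obs, max_rank=max_rank)
    t_elim = elimination_times(obs, t_elim_edges)
    dead_hist, alive_hist = contact_count_distributions(obs)
    tot_d, tot_a, sing_d, sing_a = contact_duration_distributions(obs, dur_edges)
    return ReadoutSet(
        kill_prob_by_rank=probs,
        rank_population=at_least,
        t_elim=t_elim,
        n_contacts_dead=dead_hist,
        n_contacts_alive=alive_hist,
        total_dur_dead=tot_d,
        total_dur_alive=tot_a,
        single_dur_dead=sing_d,
        single_dur_alive=sing_a,
        t_elim_edges=t_elim_edges,
        dur_edges=dur_edges,
        pckr=pckr(obs),
        fraction_killed=fraction_killed(obs),
        fraction_never_contacted=fraction_never_contacted(obs),
        n_dead=sum(t.dead for t in obs.targets),
        n_alive=sum(not t.dead for t in obs.targets),
    )


def _pad(vectors: list[np.ndarray]) -> np.ndarray:
    """Stack vectors of unequal length, right-padding with zeros."""
    width = max(len(v) for v in vectors)
    out = np.zeros((len(vectors), width))
    for i, v in enumerate(vectors):
        out[i, : len(v)] = v
    return out


def average_readouts(readouts: list[ReadoutSet]) -> ReadoutSet:
    """Element-wise mean of replicate ReadoutSets (zero-padded to align)."""
    if not readouts:
        raise ValueError("no readouts to average")
    first = readouts[0]
    kwargs = {}
    for name in DATASET_NAMES:
        kwargs[name] = _pad([getattr(r, name) for r in readouts]).mean(axis=0)
    return ReadoutSet(
        rank_population=_pad([r.rank_population for r in readouts]).mean(axis=0),
        t_elim_edges=first.t_elim_edges,
        dur_edges=first.dur_edges,
        pckr=float(np.mean([r.pckr for r in readouts])),
        fraction_killed=float(np.mean([r.fraction_killed for r in readouts])),
        fraction_never_contacted=float(
            np.mean([r.fraction_never_contacted for r in readouts])
        ),
        n_dead=int(round(np.mean([r.n_dead for r in readouts]))),
        n_alive=int(round(np.mean([r.n_alive for r in readouts]))),
        **kwargs,
    )
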