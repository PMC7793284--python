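"""Per-tick scheduler tying motility, contacts and death hypotheses together.

Each 0.1-min tick executes, in order:

(a) free CTLs move (persistent random walk with hard-core collisions),
(b) contacts are initiated for CTL–target pairs in interaction range,
(c) contacts whose scheduled duration elapsed terminate and — for the
    probabilistic hypotheses — trigger an independent Bernoulli death
    decision per ending contact,
(d) damage hypotheses integrate damage, death clocks count down, and targets
    whose clock expired are removed (ending their remaining contacts).

Neighbourhood bookkeeping: candidate collision partners and in-reach targets
are cached per CTL and rebuilt every few ticks with a travel margin, so the
per-tick work is a short python pass over the cells.  CTLs with no candidate
within one tick's reach are translated directly (their updates commute);
the few with nearby cells are advanced one by one in a fresh random
permutation to avoid ordering bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import CTLState, TargetCellState, advance_free_ctl, build_arena
from .config import ContactDurationModel, SimulationConfig
from .contacts import ContactEvent, bind_contact, progress_contacts
from .hypotheses import HypothesisSpec, apply_damage_step, contact_end_kill_probability, damage_rate_for_target, initialize_heterogeneity
from .motility import MotilityModel, random_unit_vector, reorient_direction

__all__ = ["SimulationState", "SimulationResult", "step_simulation", "run_simulation", "events_dataframe"]

_NBR_REBUILD_TICKS = 5


@dataclass
class SimulationState:
    """Mutable state of one running simulation."""

    config: SimulationConfig
    hyp: HypothesisSpec
    motility: MotilityModel
    duration_model: ContactDurationModel
    rng: np.random.Generator
    ctls: list[CTLState]
    targets: list[TargetCellState]
    time: float = 0.0
    open_contacts: list[ContactEvent] = field(default_factory=list)
    events: list[ContactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ctls_by_id = {c.id: c for c in self.ctls}
        self._targets_by_id = {t.id: t for t in self.targets}
        cfg = self.config
        n_ctl = len(self.ctls)
        n_all = n_ctl + len(self.targets)
        # master position array; cell .position attributes become views into it
        self._pos = np.empty((n_all, 3))
        for i, c in enumerate(self.ctls):
            self._pos[i] = c.position
            c.position = self._pos[i]
        for j, t in enumerate(self.targets):
            self._pos[n_ctl + j] = t.position
            t.position = self._pos[n_ctl + j]
        self._n_ctl = n_ctl
        self._active = np.ones(n_all, dtype=bool)
        self._radii_vs_ctl = np.empty(n_all)
        self._radii_vs_ctl[:n_ctl] = cfg.C_CF * 2.0 * cfg.R_T
        self._radii_vs_ctl[n_ctl:] = cfg.C_CF * (cfg.R_T + cfg.R_I)
        self._max_step = cfg.dt * float(self.motility.speed_hist.edges[-1])
        self._nbr: list[np.ndarray] = []
        self._tgt_nbr: list[np.ndarray] = []
        self._nbr_age = 10**9  # force a rebuild on the first tick

    def target(self, target_id: int) -> TargetCellState:
        return self._targets_by_id[target_id]

    def ctl(self, ctl_id: int) -> CTLState:
        return self._ctls_by_id[ctl_id]

    def _rebuild_neighbors(self) -> None:
        """Cache, per CTL, nearby obstacle cells and in-reach targets.

        Margins cover the maximum travel until the next rebuild, so the
        caches are supersets of the exact per-tick neighbourhoods.
        """
        cfg = self.config
        n_ctl = self._n_ctl
        if n_ctl == 0:
            self._nbr_age = 0
            return
        pos = self._pos
        cpos = pos[:n_ctl]
        dx = pos[:, 0][None, :] - cpos[:, 0][:, None]
        dx -= cfg.X_dim * np.rint(dx / cfg.X_dim)
        dy = pos[:, 1][None, :] - cpos[:, 1][:, None]
        dy -= cfg.Y_dim * np.rint(dy / cfg.Y_dim)
        dz = pos[:, 2][None, :] - cpos[:, 2][:, None]
        d2 = dx * dx + dy * dy + dz * dz
        margin = 2.0 * _NBR_REBUILD_TICKS * self._max_step
        reach = self._radii_vs_ctl + margin
        near = (d2 < reach[None, :] ** 2) & self._active[None, :]
        near[np.arange(n_ctl), np.arange(n_ctl)] = False
        t_reach = cfg.interaction_radius + _NBR_REBUILD_TICKS * self._max_step
        t_near = (d2[:, n_ctl:] < t_reach**2) & self._active[None, n_ctl:]
        self._nbr = [np.flatnonzero(row) for row in near]
        # target-local indices (0..N_I-1)
        self._tgt_nbr = [np.flatnonzero(row) for row in t_near]
        self._nbr_age = 0


@dataclass
class SimulationResult:
    """Event log and final cell states of one completed simulation."""

    config: SimulationConfig
    hyp: HypothesisSpec
    events: list[ContactEvent]
    ctls: list[CTLState]
    targets: list[TargetCellState]


def _move_free_ctls(state: SimulationState) -> None:
    cfg = state.config
    rng = state.rng
    dt = cfg.dt
    if state._nbr_age >= _NBR_REBUILD_TICKS:
        state._rebuild_neighbors()
    state._nbr_age += 1

    pos = state._pos
    active = state._active
    radii = state._radii_vs_ctl
    X, Y, Z = cfg.X_dim, cfg.Y_dim, cfg.Z_dim
    slow: list[int] = []

    for i, ctl in enumerate(state.ctls):
        if ctl.refractory_clock > 0.0:
            ctl.refractory_clock = max(0.0, ctl.refractory_clock - dt)
        if ctl.bound_target is not None:
            continue
        if ctl.persistence_clock >= cfg.T_pers - 1e-12:
            ctl.speed = state.motility.speed_hist.sample(rng)
            angle = state.motility.turn_hist.sample(rng)
            ctl.direction = reorient_direction(ctl.direction, angle, rng)
            ctl.persistence_clock = 0.0
        p = ctl.position
        d = ctl.direction
        step = ctl.speed * dt
        z_new = p[2] + d[2] * step
        if state._nbr[i].size or z_new <= 0.0 or z_new >= Z:
            slow.append(i)
            continue
        p[0] = (p[0] + d[0] * step) % X
        p[1] = (p[1] + d[1] * step) % Y
        p[2] = z_new
        ctl.persistence_clock += dt

    if slow:
        order = rng.permutation(len(slow)) if len(slow) > 1 else [0]
        for k in order:
            i = slow[k]
            ctl = state.ctls[i]
            obstacles = [
                (pos[j], radii[j]) for j in state._nbr[i] if active[j]
            ]
            # persistence resampling already happened in the pass above
            advance_free_ctl(
                ctl, dt, state.ctls, state.targets, cfg, state.motility, rng,
                obstacles=obstacles,
            )


def _initiate_contacts_fast(state: SimulationState, now: float) -> list[ContactEvent]:
    cfg = state.config
    zombie_ok = state.hyp.zombie_contacts
    thresh2 = cfg.interaction_radius**2
    X, Y = cfg.X_dim, cfg.Y_dim
    new_events: list[ContactEvent] = []
    for i, ctl in enumerate(state.ctls):
        if ctl.bound_target is not None or ctl.refractory_clock > 1e-12:
            continue
        cand = state._tgt_nbr[i]
        if not cand.size:
            continue
        p = ctl.position
        px, py, pz = p[0], p[1], p[2]
        best = None
        for j in cand:
            tgt = state.targets[j]
            if tgt.state == "removed" or (tgt.state == "dying" and not zombie_ok):
                continue
            if now < tgt.antigen_on_time:
                continue
            q = tgt.position
            wx = q[0] - px
            wx -= X * round(wx / X)
            wy = q[1] - py
            wy -= Y * round(wy / Y)
            wz = q[2] - pz
            d2 = wx * wx + wy * wy + wz * wz
            if d2 < thresh2 and (best is None or (d2, tgt.id) < best[:2]):
                best = (d2, tgt.id, tgt)
        if best is not None:
            new_events.append(
                bind_contact(ctl, best[2], now, state.duration_model, state.rng)
            )
    return new_events


def _start_dying(state: SimulationState, tgt: TargetCellState, now: float) -> None:
    tgt.state = "dying"
    tgt.death_clock = state.hyp.T_death


def _remove_target(state: SimulationState, tgt: TargetCellState, now: float) -> None:
    tgt.state = "removed"
    tgt.removal_time = now
    tgt.death_clock = 0.0
    state._active[state._n_ctl + tgt.id] = False
    if tgt.active_ctls:
        for ev in state.open_contacts:
            if ev.open and ev.target_id == tgt.id:
                ev.end_time = now
                ev.end_reason = "target_removed"
                ctl = state.ctl(ev.ctl_id)
                ctl.bound_target = None
                ctl.direction = random_unit_vector(state.rng)
                ctl.speed = state.motility.speed_hist.sample(state.rng)
                ctl.persistence_clock = 0.0
                ctl.refractory_clock = state.config.T_pers
        tgt.active_ctls.clear()


def step_simulation(state: SimulationState) -> SimulationState:
    """Advance the simulation by one tick (stages a–d above)."""
    cfg = state.config
    hyp = state.hyp
    rng = state.rng
    now = state.time + cfg.dt

    # (a) movement
    _move_free_ctls(state)

    # (b) contact initiation
    new_events = _initiate_contacts_fast(state, now)
    state.open_contacts.extend(new_events)
    state.events.extend(new_events)

    # (c) scheduled terminations + contact-end death decisions
    ended = progress_contacts(
        state.open_contacts, state._ctls_by_id, state._targets_by_id,
        now, cfg, state.motility, rng,
    )
    became_dying: set[int] = set()
    if hyp.is_probabilistic and ended:
        deciding = [
            ev for ev in ended
            if ev.end_reason == "scheduled" and not ev.zombie
            and state.target(ev.target_id).state == "alive"
        ]
        if len(deciding) > 1:
            deciding = [deciding[i] for i in rng.permutation(len(deciding))]
        for ev in deciding:
            tgt = state.target(ev.target_id)
            if tgt.state != "alive":
                continue  # killed by a simultaneous contact this tick
            p = contact_end_kill_probability(hyp, state.ctl(ev.ctl_id), tgt)
            if rng.random() < p:
                _start_dying(state, tgt, now)
                became_dying.add(tgt.id)

    # (d) damage accumulation, death clocks, removals
    if hyp.is_damage:
        open_by_target: dict[int, list[ContactEvent]] = {}
        for ev in state.open_contacts:
            if ev.open:
                open_by_target.setdefault(ev.target_id, []).append(ev)
        for tgt in state.targets:
            if tgt.state != "alive" or not tgt.active_ctls:
                continue
            # contacts initiated this tick have existed for zero time and
            # damage only from the next tick on (keeps the 1/d lower bound
            # on elimination times exact at tick resolution)
            active = [
                ev for ev in open_by_target.get(tgt.id, [])
                if ev.start_time < now - 1e-12
            ]
            if not active:
                continue
            if hyp.variant == "ctl_integration_damage":
                rate = damage_rate_for_target(
                    hyp, active,
                    ctl_contact_counts=[state.ctl(ev.ctl_id).contact_count for ev in active],
                )
            else:
                for ev in active:
                    ev.elapsed = ev.elapsed_at(now)  # consumed by saturated variant
                rate = damage_rate_for_target(hyp, active)
            _, triggered = apply_damage_step(tgt, rate, hyp, cfg.dt)
            if triggered:
                _start_dying(state, tgt, now)
                became_dying.add(tgt.id)

    for tgt in state.targets:
        if tgt.state != "dying":
            continue
        if tgt.id not in became_dying:
            tgt.death_clock -= cfg.dt
        if tgt.death_clock <= 1e-9:
            _remove_target(state, tgt, now)

    state.open_contacts = [ev for ev in state.open_contacts if ev.open]
    state.time = now
    return state


def run_simulation(
    config: SimulationConfig,
    hyp: HypothesisSpec,
    motility: MotilityModel,
    duration_model: ContactDurationModel | None = None,
    rng: np.random.Generator | int | None = None,
    on_tick=None,
    prepare_cells=None,
) -> SimulationResult:
    """Run one full simulation of ``config.T_Sim`` minutes.

    ``on_tick(state)`` (optional) is called after every tick — used for
    invariant audits and snapshot export.  ``prepare_cells(ctls, targets,
    rng)`` (optional) adjusts freshly placed cells before the run, e.g. to
    delay antigen expression in priming scenarios.  Contacts still open at
    the end of the run are closed with reason ``window_end``.
    """
    if duration_model is None:
        duration_model = ContactDurationModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    ctls, targets = build_arena(config, motility, rng)
    initialize_heterogeneity(hyp, ctls, targets, rng)
    if prepare_cells is not None:
        prepare_cells(ctls, targets, rng)
    state = SimulationState(
        config=config, hyp=hyp, motility=motility,
        duration_model=duration_model, rng=rng, ctls=ctls, targets=targets,
    )
    for _ in range(config.n_ticks):
        step_simulation(state)
        if on_tick is not None:
            on_tick(state)
    for ev in state.open_contacts:
        ev.end_time = state.time
        ev.end_reason = "window_end"
    state.open_contacts = []
    return SimulationResult(
        config=config, hyp=hyp, events=state.events, ctls=state.ctls, targets=state.targets
    )


def snapshot_writer(path):
    """``on_tick`` callback appending one CSV row per cell per tick.

    Columns: time_min, cell_id, cell_type, x, y, z, state.  Off by default —
    pass the returned callback to :func:`run_simulation` to enable.
    """
    path = open(path, "w")
    path.write("time_min,cell_id,cell_type,x,y,z,state\n")

    def on_tick(state: SimulationState) -> None:
        t = state.time
        for c in state.ctls:
            cell_state = "bound" if c.bound_target is not None else "free"
            path.write(
                f"{t:.1f},{c.id},ctl,{c.position[0]:.3f},{c.position[1]:.3f},"
                f"{c.position[2]:.3f},{cell_state}\n"
            )
        for tg in state.targets:
            path.write(
                f"{t:.1f},{tg.id},target,{tg.position[0]:.3f},{tg.position[1]:.3f},"
                f"{tg.position[2]:.3f},{tg.state}\n"
            )

    on_tick.close = path.close
    return on_tick


def events_dataframe(result: SimulationResult) -> pd.DataFrame:
    """Event log as a DataFrame (one row per contact)."""
    return pd.DataFrame(
        {
            "ctl_id": [ev.ctl_id for ev in result.events],
            "target_id": [ev.target_id for ev in result.events],
            "start_min": [ev.start_time for ev in result.events],
            "end_min": [ev.end_time for ev in result.events],
            "scheduled_min": [ev.scheduled_duration for ev in result.events],
            "zombie": [int(ev.zombie) for ev in result.events],
            "end_reason": [ev.end_reason for ev in result.events],
        }
    )
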