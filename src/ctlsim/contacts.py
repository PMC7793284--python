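"""Initiation, timing and termination of CTL–target interactions.

A free, non-refractory CTL within ``I_CF*(R_T+R_I)`` of an eligible target
initiates a contact, halts, and stays bound until a pre-drawn log-normal
duration elapses or the target is removed, whichever comes first.  A CTL is
monogamous (one open contact at a time); a target can hold many simultaneous
contacts.  Contacts newly initiated with an already-dying target are
"zombie contacts" — allowed only when the hypothesis enables them, and never
contributing to death decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import CTLState, TargetCellState
from .config import ContactDurationModel, SimulationConfig, sample_contact_duration
from .hypotheses import HypothesisSpec
from .motility import MotilityModel, random_unit_vector

__all__ = ["ContactEvent", "initiate_contacts", "progress_contacts", "sample_contact_duration"]


@dataclass
class ContactEvent:
    """One CTL–target interaction from initiation to termination."""

    ctl_id: int
    target_id: int
    start_time: float
    scheduled_duration: float
    end_time: float | None = None
    end_reason: str | None = None   # scheduled | target_removed | window_end
    zombie: bool = False            # initiated while the target was already dying

    @property
    def open(self) -> bool:
        return self.end_time is None

    def elapsed_at(self, time: float) -> float:
        return time - self.start_time


def initiate_contacts(
    ctls: list[CTLState],
    targets: list[TargetCellState],
    hyp: HypothesisSpec,
    time: float,
    config: SimulationConfig,
    duration_model: ContactDurationModel,
    rng: np.random.Generator,
) -> list[ContactEvent]:
    """Start contacts for every eligible CTL–target pair in interaction range.

    Eligible targets are alive (or dying, when zombie contacts are enabled)
    and antigen-visible.  Each CTL binds at most its nearest eligible target
    (ties broken by lower target id); the CTL halts and both contact counters
    increment.  Distances use the periodic x/y metric.
    """
    candidates = [
        t
        for t in targets
        if time >= t.antigen_on_time
        and (t.state == "alive" or (t.state == "dying" and hyp.zombie_contacts))
    ]
    free = [c for c in ctls if c.bound_target is None and c.refractory_clock <= 1e-12]
    if not candidates or not free:
        return []
    tpos = np.array([t.position for t in candidates])
    cpos = np.array([c.position for c in free])
    dx = cpos[:, 0][:, None] - tpos[:, 0][None, :]
    dx -= config.X_dim * np.rint(dx / config.X_dim)
    dy = cpos[:, 1][:, None] - tpos[:, 1][None, :]
    dy -= config.Y_dim * np.rint(dy / config.Y_dim)
    dz = cpos[:, 2][:, None] - tpos[:, 2][None, :]
    dist2 = dx * dx + dy * dy + dz * dz
    threshold = config.interaction_radius
    hits = dist2 < threshold**2
    new_events: list[ContactEvent] = []
    for i in np.flatnonzero(hits.any(axis=1)):
        ctl = free[i]
        in_range = np.flatnonzero(hits[i])
        # nearest eligible target wins; ties by lower target id
        order = sorted(in_range, key=lambda j: (dist2[i, j], candidates[j].id))
        new_events.append(bind_contact(ctl, candidates[order[0]], time, duration_model, rng))
    return new_events


def bind_contact(
    ctl: CTLState,
    tgt: TargetCellState,
    time: float,
    duration_model: ContactDurationModel,
    rng: np.random.Generator,
) -> ContactEvent:
    """Open a contact: halt the CTL, bump both counters, draw a duration."""
    ev = ContactEvent(
        ctl_id=ctl.id,
        target_id=tgt.id,
        start_time=time,
        scheduled_duration=sample_contact_duration(duration_model, rng),
        zombie=tgt.state == "dying",
    )
    ctl.bound_target = tgt.id
    ctl.contact_count += 1
    tgt.contact_count += 1
    tgt.active_ctls.add(ctl.id)
    if tgt.first_contact_time is None:
        tgt.first_contact_time = time
    return ev


def progress_contacts(
    open_contacts: list[ContactEvent],
    ctls_by_id: dict[int, CTLState],
    targets_by_id: dict[int, TargetCellState],
    time: float,
    config: SimulationConfig,
    motility: MotilityModel,
    rng: np.random.Generator,
) -> list[ContactEvent]:
    """Terminate contacts whose time is up or whose target was removed.

    On termination the CTL is released with a fresh uniform direction, a new
    speed draw, a reset persistence clock, and a refractory period of one
    persistence time during which it may not initiate new contacts.
    """
    ended: list[ContactEvent] = []
    for ev in open_contacts:
        if not ev.open:
            continue
        tgt = targets_by_id[ev.target_id]
        if tgt.state == "removed":
            ev.end_time = tgt.removal_time if tgt.removal_time is not None else time
            ev.end_reason = "target_removed"
        elif ev.elapsed_at(time) >= ev.scheduled_duration - 1e-12:
            # detachment happened at the scheduled time within this tick
            ev.end_time = ev.start_time + ev.scheduled_duration
            ev.end_reason = "scheduled"
        else:
            continue
        ended.append(ev)
        tgt.active_ctls.discard(ev.ctl_id)
        ctl = ctls_by_id[ev.ctl_id]
        ctl.bound_target = None
        ctl.direction = random_unit_vector(rng)
        ctl.speed = motility.speed_hist.sample(rng)
        ctl.persistence_clock = 0.0
        ctl.refractory_clock = config.T_pers
    return ended
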