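"""The nine target-cell death hypotheses and damage closed forms.

Probabilistic variants decide death by a Bernoulli draw at the natural end of
each CTL–target contact; damage variants accumulate a dimensionless damage
``I`` during contacts and trigger death when ``I`` reaches 1.  Once death is
decided the cell persists, visibly intact, for ``T_death`` minutes before
being removed ("disrupted").  New contacts initiated during that dying phase
are "zombie contacts": they never influence the death decision but are seen
by an observer counting contacts.

Variants
--------
``null``
    Constant kill probability ``p`` per contact.
``infected_integration``
    Kill probability ``k_I * C_I`` with ``C_I`` the target's contact count
    (including the current contact).
``ctl_integration``
    Kill probability ``k_T * C_T`` with ``C_T`` the CTL's contact count;
    with ``negative_modulation`` the exhaustion form ``k_T / C_T``.
``ctl_heterogeneity`` / ``infected_heterogeneity``
    Per-cell constant probabilities drawn once from Normal(k_m, k_s) /
    Normal(d_m, d_s), clamped to [0, 1].
``constant_damage``
    dI/dt = n_CTL(t) * d.
``saturated_damage``
    Each contact damages at rate ``d`` only while its elapsed time is below
    ``T_max`` (per-contact granule exhaustion).
``damage_repair``
    dI/dt = n_CTL(t) * d − r * I.
``ctl_integration_damage``
    dI/dt = Σ over active contacts of k_T * C_T of the contacting CTL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HypothesisSpec",
    "PROBABILISTIC_VARIANTS",
    "DAMAGE_VARIANTS",
    "VARIANTS",
    "initialize_heterogeneity",
    "contact_end_kill_probability",
    "damage_rate_for_target",
    "apply_damage_step",
    "damage_closed_form_first_contact",
    "time_to_complete_damage",
]

PROBABILISTIC_VARIANTS = frozenset(
    {
        "null",
        "infected_integration",
        "ctl_integration",
        "ctl_heterogeneity",
        "infected_heterogeneity",
    }
)
DAMAGE_VARIANTS = frozenset(
    {"constant_damage", "saturated_damage", "damage_repair", "ctl_integration_damage"}
)
VARIANTS = PROBABILISTIC_VARIANTS | DAMAGE_VARIANTS

# Parameters each variant actually consults (besides T_death / flags).
_VARIANT_PARAMS: dict[str, tuple[str, ...]] = {
    "null": ("p",),
    "infected_integration": ("k_I",),
    "ctl_integration": ("k_T",),
    "ctl_heterogeneity": ("k_m", "k_s"),
    "infected_heterogeneity": ("d_m", "d_s"),
    "constant_damage": ("d",),
    "saturated_damage": ("d", "T_max"),
    "damage_repair": ("d", "r"),
    "ctl_integration_damage": ("k_T",),
}


@dataclass(frozen=True)
class HypothesisSpec:
    """One death mechanism with its killing parameters and removal delay."""

    variant: str
    p: float | None = None
    k_I: float | None = None
    k_T: float | None = None
    k_m: float | None = None
    k_s: float | None = None
    d_m: float | None = None
    d_s: float | None = None
    d: float | None = None
    r: float | None = None
    T_max: float | None = None
    T_death: float = 15.0
    zombie_contacts: bool = False
    negative_modulation: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}"
            )
        missing = [n for n in _VARIANT_PARAMS[self.variant] if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"variant {self.variant!r} requires parameter(s): {', '.join(missing)}"
            )
        for name in _VARIANT_PARAMS[self.variant]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.T_death < 0:
            raise ValueError("T_death must be nonnegative")

    @property
    def is_probabilistic(self) -> bool:
        return self.variant in PROBABILISTIC_VARIANTS

    @property
    def is_damage(self) -> bool:
        return self.variant in DAMAGE_VARIANTS

    @property
    def free_parameter_count(self) -> int:
        """Fitted parameters: the variant's killing parameters plus T_death."""
        return len(_VARIANT_PARAMS[self.variant]) + 1

    @property
    def killing_parameters(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in _VARIANT_PARAMS[self.variant]}

    def replace(self, **kwargs) -> "HypothesisSpec":
        return replace(self, **kwargs)


def initialize_heterogeneity(hyp: HypothesisSpec, ctls, targets, rng: np.random.Generator):
    """Assign per-cell kill/death probabilities for the heterogeneity variants.

    Draws are independent Normal(mean, sd), clamped to [0, 1] without redraw.
    No-op for every other variant.
    """
    if hyp.variant == "ctl_heterogeneity":
        for ctl in ctls:
            ctl.kill_param = float(np.clip(rng.normal(hyp.k_m, hyp.k_s), 0.0, 1.0))
    elif hyp.variant == "infected_heterogeneity":
        for tgt in targets:
            tgt.susceptibility = float(np.clip(rng.normal(hyp.d_m, hyp.d_s), 0.0, 1.0))
    return ctls, targets


def contact_end_kill_probability(hyp: HypothesisSpec, ctl, target) -> float:
    """Death probability applied when a (non-zombie) contact ends naturally.

    Linear integration forms are clamped to [0, 1].  ``C_T``/``C_I`` include
    the contact that is just ending.
    """
    if not hyp.is_probabilistic:
        raise ValueError(f"variant {hyp.variant!r} has no contact-end death decision")
    if hyp.variant == "null":
        x = hyp.p
    elif hyp.variant == "infected_integration":
        x = hyp.k_I * target.contact_count
    elif hyp.variant == "ctl_integration":
        if hyp.negative_modulation:
            x = hyp.k_T / max(ctl.contact_count, 1)
        else:
            x = hyp.k_T * ctl.contact_count
    elif hyp.variant == "ctl_heterogeneity":
        if ctl.kill_param is None:
            raise ValueError("CTL heterogeneity not initialised (kill_param unset)")
        x = ctl.kill_param
    else:  # infected_heterogeneity
        if target.susceptibility is None:
            raise ValueError("target heterogeneity not initialised (susceptibility unset)")
        x = target.susceptibility
    return min(1.0, max(0.0, float(x)))


def damage_rate_for_target(
    hyp: HypothesisSpec,
    active_contacts: Sequence,
    ctl_contact_counts: Iterable[int] | None = None,
) -> float:
    """Instantaneous damage rate (per min) from the contacts on one target.

    ``active_contacts`` carries, per contact, the elapsed time (attribute
    ``elapsed`` or item 0 of a tuple) used by the saturated variant.  For the
    CTL-integration-damage variant ``ctl_contact_counts`` gives each
    contacting CTL's contact count.
    """
    if not hyp.is_damage:
        raise ValueError(f"variant {hyp.variant!r} is not a damage variant")
    n = len(active_contacts)
    if hyp.variant == "constant_damage" or hyp.variant == "damage_repair":
        return n * hyp.d
    if hyp.variant == "saturated_damage":
        active = 0
        for c in active_contacts:
            elapsed = c.elapsed if hasattr(c, "elapsed") else c[0]
            if elapsed < hyp.T_max:
                active += 1
        return active * hyp.d
    # ctl_integration_damage
    if ctl_contact_counts is None:
        raise ValueError("ctl_integration_damage needs the contacting CTLs' contact counts")
    return hyp.k_T * float(sum(ctl_contact_counts))


def apply_damage_step(target, rate: float, hyp: HypothesisSpec, dt: float):
    """Forward-Euler damage update; returns (new damage, death triggered).

    ``I ← I + rate·dt − r·I·dt`` (repair term only for the damage_repair
    variant), floored at 0.  Death is triggered once ``I ≥ 1``.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    damage = target.damage + rate * dt
    if hyp.variant == "damage_repair":
        damage -= hyp.r * target.damage * dt
    damage = max(0.0, damage)
    target.damage = damage
    return damage, damage >= 1.0


def damage_closed_form_first_contact(d: float, r: float, t: float) -> float:
    """Damage after ``t`` minutes of one continuous contact with repair.

    ``I(t) = (d/r)(1 − e^{−rt})`` — the analytic solution of
    dI/dt = d − rI from I(0)=0; used as the oracle for the Euler update.
    """
    if r <= 0:
        raise ValueError("r must be strictly positive (use d*t for the no-repair limit)")
    return -(d / r) * math.expm1(-r * t)  # expm1 keeps tiny repair rates accurate


def time_to_complete_damage(d: float, r: float) -> float:
    """Minutes of one continuous contact needed to reach damage 1.

    ``t = −(1/r)·ln(1 − r/d)``; the repair-free limit ``r → 0`` gives 1/d.
    Raises when ``r ≥ d`` (damage plateaus at d/r ≤ 1, never reaching 1).
    """
    if d <= 0:
        raise ValueError("d must be strictly positive")
    if r < 0:
        raise ValueError("r must be nonnegative")
    if r >= d:
        raise ValueError("damage never reaches 1 when r >= d (plateau d/r <= 1)")
    if r == 0:
        return 1.0 / d
    return -math.log1p(-r / d) / r  # log1p keeps tiny repair rates accurate
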