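"""Simulation configuration and the contact-duration model.

Defaults reproduce the reference imaging-volume setup: a 700×700×700 µm
periodic-in-x/y box, 200 CTLs placed anywhere, 250 stationary infected cells
in the top 40% of the z-axis, 0.1-min ticks over 240 simulated minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["SimulationConfig", "ContactDurationModel", "sample_contact_duration"]


@dataclass(frozen=True)
class SimulationConfig:
    """Arena geometry, cell counts and timing of one simulation.

    All lengths in µm, times in minutes.  ``I_CF`` scales the interaction
    (pseudopod reach) radius, ``C_CF`` the hard-core nuclear radius; a CTL and
    an infected cell interact below ``I_CF*(R_T+R_I)`` and collide at
    ``C_CF*(R_T+R_I)``.
    """

    X_dim: float = 700.0
    Y_dim: float = 700.0
    Z_dim: float = 700.0
    Z_lim: float = 0.4          # top fraction of z holding infected cells
    N_T: int = 200              # CTL count
    N_I: int = 250              # infected-cell count
    R_T: float = 4.8
    R_I: float = 5.1
    I_CF: float = 1.5
    C_CF: float = 0.5
    T_pers: float = 2.0         # persistence time, min
    dt: float = 0.1
    T_Sim: float = 240.0
    obs_start: float = 0.0
    obs_end: float | None = None  # defaults to T_Sim
    seed: int = 0
    n_reps: int = 30

    def __post_init__(self) -> None:
        for name in ("X_dim", "Y_dim", "Z_dim", "R_T", "R_I", "T_pers", "dt", "T_Sim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.Z_lim <= 1:
            raise ValueError("Z_lim must lie in (0, 1]")
        if not 0 < self.C_CF <= 1:
            raise ValueError("C_CF must lie in (0, 1]")
        if self.I_CF < 1:
            raise ValueError("I_CF must be >= 1")
        if self.N_T < 0 or self.N_I < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.obs_end is not None and self.obs_end <= self.obs_start:
            raise ValueError("obs_end must exceed obs_start")

    @property
    def interaction_radius(self) -> float:
        """CTL–target interaction initiation distance, ``I_CF*(R_T+R_I)``."""
        return self.I_CF * (self.R_T + self.R_I)

    @property
    def z_floor(self) -> float:
        """Lowest z at which infected cells are placed (top ``Z_lim`` fraction)."""
        return (1.0 - self.Z_lim) * self.Z_dim

    @property
    def observation_end(self) -> float:
        return self.T_Sim if self.obs_end is None else self.obs_end

    @property
    def n_ticks(self) -> int:
        return int(round(self.T_Sim / self.dt))

    def replace(self, **kwargs) -> "SimulationConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(kwargs)
        return SimulationConfig(**data)


@dataclass(frozen=True)
class ContactDurationModel:
    """Log-normal contact-duration model (parameters in log-minutes).

    ``exp(Normal(log_mean, log_sd))`` minutes; draws above ``truncation_max``
    (when set) are rejected and redrawn.  Defaults are the fitted log-normal
    with log-mean 2.1 and log-sd 1.2 (median ≈ 8.2 min).
    """

    log_mean: float = 2.1
    log_sd: float = 1.2
    truncation_max: float | None = None

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be strictly positive")
        if self.truncation_max is not None and self.truncation_max <= 0:
            raise ValueError("truncation_max must be strictly positive when set")

    def sample(self, rng: np.random.Generator) -> float:
        dur = math.exp(self.log_mean + self.log_sd * rng.standard_normal())
        if self.truncation_max is not None:
            while dur > self.truncation_max:
                dur = math.exp(self.log_mean + self.log_sd * rng.standard_normal())
        return dur

    def sample_many(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = np.exp(self.log_mean + self.log_sd * rng.standard_normal(n))
        if self.truncation_max is not None:
            bad = draws > self.truncation_max
            while bad.any():
                draws[bad] = np.exp(
                    self.log_mean + self.log_sd * rng.standard_normal(int(bad.sum()))
                )
                bad = draws > self.truncation_max
        return draws


def sample_contact_duration(model: ContactDurationModel, rng: np.random.Generator) -> float:
    """Draw one contact duration in minutes (strictly positive)."""
    return model.sample(rng)
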