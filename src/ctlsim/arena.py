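"""Cell state containers, arena construction and free-CTL movement.

The arena is a rectangular box, periodic along x and y, with impermeable z
boundaries.  CTLs are motile hard spheres (nuclear core ``C_CF * R``);
infected target cells are stationary and confined to the top ``Z_lim``
fraction of the z-axis, mimicking the imaging depth of the tissue volume the
model emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .motility import MotilityModel, random_unit_vector, reorient_direction

__all__ = ["CTLState", "TargetCellState", "build_arena", "advance_free_ctl"]

MAX_PLACEMENT_RETRIES = 100_000


@dataclass
class CTLState:
    """One cytotoxic T lymphocyte (motile killer agent)."""

    id: int
    position: np.ndarray
    direction: np.ndarray
    speed: float
    persistence_clock: float = 0.0
    refractory_clock: float = 0.0
    bound_target: int | None = None
    contact_count: int = 0          # C_T: contacts initiated so far
    kill_param: float | None = None  # per-cell kill probability (heterogeneity)

    @property
    def is_free(self) -> bool:
        return self.bound_target is None


@dataclass
class TargetCellState:
    """One stationary virus-infected target cell."""

    id: int
    position: np.ndarray
    state: str = "alive"            # alive -> dying -> removed
    damage: float = 0.0             # I, dimensionless; death at I >= 1
    contact_count: int = 0          # C_I: contacts received so far
    death_clock: float = 0.0        # min remaining until removal once dying
    susceptibility: float | None = None  # per-cell death probability
    first_contact_time: float | None = None
    removal_time: float | None = None
    antigen_on_time: float = 0.0    # invisible to CTLs before this time
    active_ctls: set = field(default_factory=set, repr=False)

    @property
    def alive(self) -> bool:
        return self.state == "alive"


def _overlaps(pos, radius, placed_pos, placed_radii, config) -> bool:
    """Nuclear overlap of a candidate against already placed cells (periodic x/y)."""
    if len(placed_pos) == 0:
        return False
    P = np.asarray(placed_pos)
    d = P - pos
    d[:, 0] -= config.X_dim * np.round(d[:, 0] / config.X_dim)
    d[:, 1] -= config.Y_dim * np.round(d[:, 1] / config.Y_dim)
    thresh = config.C_CF * (np.asarray(placed_radii) + radius)
    return bool(np.any(np.einsum("ij,ij->i", d, d) < thresh**2))


def build_arena(
    config: SimulationConfig, motility: MotilityModel, rng: np.random.Generator
) -> tuple[list[CTLState], list[TargetCellState]]:
    """Place cells without nuclear overlap and initialise CTL kinematics.

    CTLs are uniform in the whole box; targets are uniform in the top
    ``Z_lim`` fraction of z.  Each CTL starts with a speed drawn from the
    speed histogram, a uniform random direction, and a persistence clock
    uniform in ``[0, T_pers)`` to desynchronise turning.
    """
    positions: list[np.ndarray] = []
    radii: list[float] = []
    retries = 0

    def place(radius: float, z_low: float, what: str) -> np.ndarray:
        nonlocal retries
        while True:
            pos = np.array(
                [
                    rng.uniform(0.0, config.X_dim),
                    rng.uniform(0.0, config.Y_dim),
                    rng.uniform(z_low, config.Z_dim),
                ]
            )
            if not _overlaps(pos, radius, positions, radii, config):
                positions.append(pos)
                radii.append(radius)
                return pos
            retries += 1
            if retries > MAX_PLACEMENT_RETRIES:
                raise ValueError(
                    f"could not place all cells without nuclear overlap "
                    f"(failed while placing {what}; densest constraint: "
                    f"{'targets in the top Z_lim slab' if z_low > 0 else 'whole arena'})"
                )

    targets = [
        TargetCellState(id=i, position=place(config.R_I, config.z_floor, "infected cells"))
        for i in range(config.N_I)
    ]
    ctls = [
        CTLState(
            id=i,
            position=place(config.R_T, 0.0, "CTLs"),
            direction=random_unit_vector(rng),
            speed=motility.speed_hist.sample(rng),
            persistence_clock=rng.uniform(0.0, config.T_pers),
        )
        for i in range(config.N_T)
    ]
    return ctls, targets


def _first_obstacle_distance(pos, direction, step, obstacles, config) -> float:
    """Distance along ``direction`` to the first nucleus collision (inf if none).

    ``obstacles`` is a sequence of (position, collision_radius) pairs;
    positions are compared with the periodic x/y metric.
    """
    x, y, z = pos
    ux, uy, uz = direction
    best = math.inf
    X, Y = config.X_dim, config.Y_dim
    for (ox, oy, oz), R in obstacles:
        wx = ox - x
        wx -= X * round(wx / X)
        wy = oy - y
        wy -= Y * round(wy / Y)
        wz = oz - z
        s = wx * ux + wy * uy + wz * uz  # closest-approach parameter
        if s <= 0.0:
            continue  # moving away
        w2 = wx * wx + wy * wy + wz * wz
        line2 = w2 - s * s
        R2 = R * R
        if line2 >= R2:
            continue  # path misses the sphere
        t = s - math.sqrt(R2 - line2)
        if t < 0.0:
            t = 0.0  # already touching and approaching
        if t <= step and t < best:
            best = t
    return best


def advance_free_ctl(
    ctl: CTLState,
    dt: float,
    ctls: list[CTLState],
    targets: list[TargetCellState],
    config: SimulationConfig,
    motility: MotilityModel,
    rng: np.random.Generator,
    obstacles=None,
) -> CTLState:
    """Move one unbound CTL for one tick of the persistent random walk.

    If the persistence time is up, a new speed and turning angle are drawn
    first.  The CTL then travels ``speed*dt`` along its heading, truncated at
    the first nucleus collision or closed z-boundary; on a hit it forfeits the
    rest of the step, takes a uniformly random new direction and resets its
    persistence clock.  x/y wrap periodically.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if ctl.persistence_clock >= config.T_pers - 1e-12:
        ctl.speed = motility.speed_hist.sample(rng)
        angle = motility.turn_hist.sample(rng)
        ctl.direction = reorient_direction(ctl.direction, angle, rng)
        ctl.persistence_clock = 0.0

    if obstacles is None:
        obstacles = [
            (c.position, config.C_CF * (config.R_T + config.R_T))
            for c in ctls
            if c.id != ctl.id
        ] + [
            (t.position, config.C_CF * (config.R_T + config.R_I))
            for t in targets
            if t.state != "removed"
        ]

    step = ctl.speed * dt
    x, y, z = ctl.position
    ux, uy, uz = ctl.direction
    travel = step
    hit = False

    # closed z-boundaries
    if uz > 1e-15:
        t_b = (config.Z_dim - z) / uz
    elif uz < -1e-15:
        t_b = -z / uz
    else:
        t_b = math.inf
    if t_b < travel:
        travel, hit = t_b, True

    t_obs = _first_obstacle_distance((x, y, z), (ux, uy, uz), travel, obstacles, config)
    if t_obs < travel:
        travel, hit = t_obs, True
    elif t_obs == travel and t_obs < math.inf and t_obs < step:
        hit = True

    if travel > 0.0:
        # in-place write: the position may be a view into a master array
        ctl.position[0] = (x + ux * travel) % config.X_dim
        ctl.position[1] = (y + uy * travel) % config.Y_dim
        ctl.position[2] = min(max(z + uz * travel, 0.0), config.Z_dim)

    if hit or (travel < step - 1e-12):
        ctl.direction = random_unit_vector(rng)
        ctl.persistence_clock = 0.0
    else:
        ctl.persistence_clock += dt
    return ctl
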