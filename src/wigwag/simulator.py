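"""Wigwag agent simulation.

The agent models spontaneous planarian locomotion: it moves straight
ahead at constant speed (10 sim-units/s, one unit per 0.1-s tick) and
at stochastic times applies an instantaneous heading change — the
"wigwag".  Wigwag angles xi are drawn from a normal distribution and
the intervals k between wigwags from a lognormal distribution; both
draws are rounded to two decimals.  The interval is realized through an
integer countdown i: each tick with i != 0 decrements it; when i == 0
the heading receives xi and i is reset to round(10 * k) ticks (at least
one).  Wall contact is resolved by clamping to the wall and realigning
the heading along the wall tangent (see :mod:`wigwag.arena`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import FieldGeometry, FieldKind, collide_and_slide, partition_regions, wrap_angle


@dataclass(frozen=True)
class WigwagParams:
    """Behavioral parameters of the wigwag agent.

    angle_mean / angle_sd : radians
        Normal distribution of the wigwag angle xi.
    interval_logmean / interval_logsd : log-seconds
        Lognormal distribution of the wigwag interval k; the location
        and scale are in log space (median interval exp(logmean) s).
    speed : sim-units per second (default 10).
    dt : seconds per tick (default 0.1); one tick covers speed*dt units.
    """

    angle_mean: float = 0.0
    angle_sd: float = 0.3
    interval_logmean: float = 0.14
    interval_logsd: float = 0.48
    speed: float = 10.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.angle_sd < 0:
            raise ValueError("angle_sd must be >= 0")
        if self.interval_logsd < 0:
            raise ValueError("interval_logsd must be >= 0")
        if self.speed <= 0 or self.dt <= 0:
            raise ValueError("speed and dt must be positive")

    @property
    def step_length(self) -> float:
        return self.speed * self.dt


@dataclass
class AgentState:
    """Evolving simulator state: position, bearing, wigwag countdown."""

    x: float
    y: float
    theta: float
    i: int

    def __post_init__(self) -> None:
        if self.i < 0:
            raise ValueError("countdown i must be non-negative")


@dataclass(frozen=True)
class WigwagEvent:
    """A wigwag applied at a simulation tick."""

    tick: int
    angle: float  # applied xi, rounded to 0.01 rad
    interval: float  # sampled k, rounded to 0.01 s


@dataclass
class Trajectory:
    """Fixed-rate track of 2-D positions.

    ``times`` is a uniform grid with step ``dt``; ``positions`` is an
    (n, 2) float array in sim-units.  Simulated trajectories carry an
    ``event_log`` of applied wigwags; tracked (or noise-jittered) data
    have an empty log.
    """

    times: np.ndarray
    positions: np.ndarray
    field: Optional[FieldGeometry] = None
    event_log: List[WigwagEvent] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (len(self.times), 2):
            raise ValueError("times must be 1-D and positions (n, 2)")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if dts.min() <= 0 or np.ptp(dts) > 1e-9:
                raise ValueError("times must be a strictly increasing uniform grid")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trajectory has fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def _sample_wigwag_event(params: WigwagParams, rng: np.random.Generator) -> Tuple[float, float, int]:
    """Draw one (xi, k) pair, rounded to two decimals, and the countdown."""
    xi = round(rng.normal(params.angle_mean, params.angle_sd), 2)
    k = round(rng.lognormal(params.interval_logmean, params.interval_logsd), 2)
    i = max(1, round(10.0 * k))
    return xi, k, i


def step(
    state: AgentState,
    params: WigwagParams,
    field: FieldGeometry,
    rng: np.random.Generator,
) -> Tuple[AgentState, Optional[WigwagEvent], bool]:
    """Advance the agent by one tick.

    Returns the new state, the wigwag event if one fired this tick, and
    whether the move ended in wall contact.  The tick passed to the
    event is 0; callers renumber it when logging.
    """
    theta = state.theta
    event = None
    if state.i == 0:
        xi, k, i = _sample_wigwag_event(params, rng)
        theta = wrap_angle(theta + xi)
        event = WigwagEvent(tick=0, angle=xi, interval=k)
    else:
        i = state.i - 1
    L = params.step_length
    proposed = (state.x + L * math.sin(theta), state.y + L * math.cos(theta))
    (nx, ny), ntheta, contact = collide_and_slide(field, (state.x, state.y), proposed, theta, rng)
    return AgentState(nx, ny, ntheta, i), event, contact


def default_start(field: FieldGeometry) -> Tuple[float, float]:
    """Arena start point: the center, or (175, 0) between the donut walls."""
    if field.kind is FieldKind.DONUT:
        return ((field.inner_radius + field.outer_radius) / 2.0, 0.0)
    return (0.0, 0.0)


def simulate(
    params: WigwagParams,
    field: FieldGeometry,
    duration_s: float,
    seed: int | np.random.Generator,
    start: Optional[Tuple[float, float]] = None,
    start_theta: Optional[float] = None,
) -> Trajectory:
    """Run the wigwag agent for ``duration_s`` seconds.

    The trajectory has floor(duration/dt) + 1 samples on the uniform dt
    grid.  ``start`` defaults to the arena center (the mid-annulus
    point (175, 0) for the donut); ``start_theta`` defaults to a uniform
    random bearing.  The initial countdown is sampled from the interval
    distribution.  Identical (params, field, seed) give bit-identical
    output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if start is None:
        start = default_start(field)
    if not field.contains(*start):
        raise ValueError(f"start {start} lies outside the field")
    if start_theta is None:
        start_theta = float(rng.uniform(0.0, 2.0 * math.pi))
    _, _, i0 = _sample_wigwag_event(params, rng)

    n_steps = int(math.floor(duration_s / params.dt))
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    state = AgentState(start[0], start[1], wrap_angle(start_theta), i0)
    events: List[WigwagEvent] = []
    for t in range(1, n_steps + 1):
        state, event, _ = step(state, params, field, rng)
        if event is not None:
            events.append(WigwagEvent(tick=t, angle=event.angle, interval=event.interval))
        pos[t, 0] = state.x
        pos[t, 1] = state.y
    times = np.arange(n_steps + 1) * params.dt
    return Trajectory(times=times, positions=pos, field=field, event_log=events)


def sweep(
    param_grid: Sequence[WigwagParams] | dict,
    field: FieldGeometry,
    n_reps: int,
    duration_s: float,
    seed: int,
    wall_margin_mm: float = 5.0,
) -> pd.DataFrame:
    """Wall-preference index over a grid of wigwag parameters.

    ``param_grid`` is either a sequence of :class:`WigwagParams` or a
    dict mapping WigwagParams field names to value lists (full factorial
    product).  Each grid point is simulated ``n_reps`` times with
    replicate seeds spawned deterministically from ``seed``.  Returns a
    tidy frame with one row per replicate (columns: the varied
    parameters, ``rep``, ``wall_index``) so both replicate-level values
    and per-point summaries are available.
    """
    from .metrics import preference_indices

    if isinstance(param_grid, dict):
        if not param_grid:
            raise ValueError("empty parameter grid")
        keys = list(param_grid)
        combos = list(itertools.product(*(param_grid[k] for k in keys)))
        grid = [WigwagParams(**dict(zip(keys, combo))) for combo in combos]
        varied = keys
    else:
        grid = list(param_grid)
        varied = ["angle_mean", "angle_sd", "interval_logmean", "interval_logsd"]
    if not grid:
        raise ValueError("empty parameter grid")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    partition = partition_regions(field, wall_margin_mm)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid) * n_reps)
    rows = []
    for gi, params in enumerate(grid):
        for rep in range(n_reps):
            rng = np.random.default_rng(children[gi * n_reps + rep])
            traj = simulate(params, field, duration_s, rng)
            pref = preference_indices(traj, partition)
            row = {name: getattr(params, name) for name in varied}
            row.update({"rep": rep, "wall_index": pref.wall_index})
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame, by: Iterable[str]) -> pd.DataFrame:
    """Mean +/- SD of the wall index per grid point of a sweep table."""
    g = table.groupby(list(by))["wall_index"]
    out = g.agg(mean_wall_index="mean", sd_wall_index="std", n="size").reset_index()
    return out
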