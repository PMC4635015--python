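"""Trajectory statistics for wall-preference analysis.

All dwell times are computed by sample counting on the fixed 0.1-s
grid: a region's time is (number of samples classified into it) * dt,
and the total assay time is n_samples * dt.  No sub-tick interpolation
is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .arena import (
    FieldGeometry,
    MM_PER_UNIT,
    Region,
    RegionPartition,
    _tangent_candidates,
    classify_points,
    wrap_angle,
)
from .simulator import Trajectory


@dataclass(frozen=True)
class PreferenceResult:
    """Region dwell times and the two preference indices.

    wall_index = T_w / T, central_index = T_c / T.
    """

    T: float
    T_w: float
    T_c: float
    wall_index: float
    central_index: float


def region_times(traj: Trajectory, partition: RegionPartition) -> dict[Region, float]:
    """Dwell time per region label, by sample counting."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    labels = classify_points(partition, traj.positions)
    dt = traj.dt
    out: dict[Region, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + dt
    return out


def preference_indices(traj: Trajectory, partition: RegionPartition) -> PreferenceResult:
    """Wall- and central-preference indices of a trajectory."""
    times = region_times(traj, partition)
    T = len(traj) * traj.dt
    T_w = times.get(Region.WALL, 0.0)
    T_c = times.get(Region.CENTRAL, 0.0)
    return PreferenceResult(T=T, T_w=T_w, T_c=T_c, wall_index=T_w / T, central_index=T_c / T)


def tn_ratio(traj: Trajectory) -> float:
    """Path length divided by net start-to-end displacement (>= 1).

    1 for perfectly straight motion; larger values indicate tortuous
    paths.
    """
    if len(traj) < 2:
        raise ValueError("tn_ratio requires at least 2 points")
    steps = np.diff(traj.positions, axis=0)
    total = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = float(np.hypot(*(traj.positions[-1] - traj.positions[0])))
    if net == 0.0:
        raise ValueError("net displacement is zero; T/N ratio undefined")
    return total / net


@dataclass(frozen=True)
class WallEpisode:
    """One stay in the wall band, from contact to detachment.

    ``t_detach`` is the time of the first sample back outside the band;
    an episode still running at assay end is open (``t_detach`` None)
    and its dwell is the remaining assay time.
    """

    t_contact: float
    t_detach: Optional[float]
    dwell: float

    @property
    def open(self) -> bool:
        return self.t_detach is None


def wall_episodes(
    traj: Trajectory, partition: RegionPartition
) -> Tuple[List[WallEpisode], float]:
    """Wall-band visits of a trajectory and their mean dwell.

    Open trailing episodes are included in the mean (animals often
    remain at the wall when the assay ends).  Returns ([], nan) for a
    trajectory that never enters the band.
    """
    labels = classify_points(partition, traj.positions)
    in_band = np.array([lab is Region.WALL for lab in labels])
    episodes: List[WallEpisode] = []
    t = traj.times
    start: Optional[int] = None
    for j, flag in enumerate(in_band):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            episodes.append(
                WallEpisode(t_contact=t[start], t_detach=t[j], dwell=float(t[j] - t[start]))
            )
            start = None
    if start is not None:
        episodes.append(
            WallEpisode(t_contact=t[start], t_detach=None, dwell=float(t[-1] - t[start]))
        )
    mean_dwell = float(np.mean([e.dwell for e in episodes])) if episodes else math.nan
    return episodes, mean_dwell


def _headings(positions: np.ndarray) -> np.ndarray:
    """Per-step bearings atan2(dx, dy) of consecutive positions."""
    d = np.diff(positions, axis=0)
    return np.arctan2(d[:, 0], d[:, 1])


def incidence_reflection(
    traj: Trajectory, field: Optional[FieldGeometry] = None, atol: float = 1e-6
) -> List[Tuple[float, float]]:
    """(incidence, reflection) angle pairs at each wall-contact event, degrees.

    A contact event is a sample on the wall (within ``atol`` sim-units)
    whose predecessor was off the wall.  Angles are measured against
    the wall tangent direction nearest the incoming heading: incidence
    is the unsigned angle between the pre-contact heading (one tick
    before contact) and that tangent, reflection the signed angle
    between the post-contact heading (one tick after) and the same
    tangent.  Tangent-aligned sliding therefore gives reflection ~ 0
    for any incidence.
    """
    field = field if field is not None else traj.field
    if field is None or not field.bounded:
        raise ValueError("incidence/reflection requires a bounded field")
    pos = traj.positions
    on_wall = np.array([field.wall_distance(x, y) <= atol for x, y in pos])
    h = _headings(pos)
    pairs: List[Tuple[float, float]] = []
    for t in range(1, len(pos) - 1):
        if not (on_wall[t] and not on_wall[t - 1]):
            continue
        pre = h[t - 1]  # bearing of the step that reached the wall
        post = h[t]  # bearing of the first step along the wall
        cands = _tangent_candidates(field, pos[t, 0], pos[t, 1])
        tangent = min(cands, key=lambda c: abs(wrap_angle(c - pre)))
        incidence = abs(wrap_angle(pre - tangent))
        reflection = wrap_angle(post - tangent)
        pairs.append((math.degrees(incidence), math.degrees(reflection)))
    return pairs


class Kinematics(NamedTuple):
    speeds: np.ndarray  # sim-units/s, one per tick
    total_distance: float  # sim-units
    time_to_first_wall: Optional[float]  # s, first entry into the wall band


def kinematics(traj: Trajectory, partition: RegionPartition) -> Kinematics:
    """Per-tick speeds, path length, and time of first wall-band entry."""
    if len(traj) < 2:
        raise ValueError("kinematics requires at least 2 points")
    steps = np.diff(traj.positions, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    labels = classify_points(partition, traj.positions)
    first = None
    for j, lab in enumerate(labels):
        if lab is Region.WALL:
            first = float(traj.times[j])
            break
    return Kinematics(
        speeds=lengths / traj.dt,
        total_distance=float(lengths.sum()),
        time_to_first_wall=first,
    )


class WigwagExtraction(NamedTuple):
    angles: np.ndarray  # turn angles, rad
    intervals: np.ndarray  # inter-turn times, s
    ticks: np.ndarray  # sample index at which each turn was applied


def extract_wigwag(traj: Trajectory, min_turn_rad: float = 0.005) -> WigwagExtraction:
    """Recover wigwag events from a position track.

    Heading is computed per tick from consecutive positions; a turn
    event is any tick where the absolute heading change exceeds
    ``min_turn_rad``.  Returns the turn angles and the times between
    consecutive turns.  Intended for open-field (or pre-wall-contact)
    segments where heading changes come only from wigwags.
    """
    if len(traj) < 3:
        raise ValueError("extract_wigwag requires at least 3 points")
    h = _headings(traj.positions)
    turns = np.array([wrap_angle(b - a) for a, b in zip(h[:-1], h[1:])])
    idx = np.nonzero(np.abs(turns) > min_turn_rad)[0]
    # turns[j] compares the steps ending at samples j+1 and j+2; the new
    # heading first takes effect at sample j+2, which is the event tick
    ticks = idx + 2
    angles = turns[idx]
    intervals = np.diff(ticks) * traj.dt
    return WigwagExtraction(angles=angles, intervals=intervals, ticks=ticks)


# -- occupancy KDE -----------------------------------------------------


@dataclass(frozen=True)
class OccupancyGrid:
    """Occupancy probability mass on a regular grid of square cells.

    ``density`` has shape (ny, nx) indexed [iy, ix]; entries are
    non-negative and sum to 1.  ``bandwidth_mm`` is the isotropic
    Gaussian kernel bandwidth used.
    """

    x_centers: np.ndarray  # mm
    y_centers: np.ndarray  # mm
    density: np.ndarray
    cell_mm: float
    bandwidth_mm: float


def _gauss2(sq_dist: np.ndarray, h: float) -> np.ndarray:
    return np.exp(-sq_dist / (2.0 * h * h)) / (2.0 * math.pi * h * h)


def _lscv_score(sq_dist: np.ndarray, n: int, h: float) -> float:
    """Least-squares cross-validation score for bandwidth h.

    ``sq_dist`` holds the n*n pairwise squared distances (diagonal
    included).  Uses the closed form for Gaussian kernels:
    integral(fhat^2) - 2 * mean of leave-one-out densities.
    """
    int_f2 = _gauss2(sq_dist, h * math.sqrt(2.0)).sum() / (n * n)
    off_diag = _gauss2(sq_dist, h).sum() - n * _gauss2(np.zeros(1), h)[0]
    cv = 2.0 * off_diag / (n * (n - 1))
    return float(int_f2 - cv)


def lscv_bandwidth(points_mm: np.ndarray, max_points: int = 1500) -> float:
    """LSCV-optimal isotropic bandwidth (mm) for a 2-D point set.

    The score is minimized by golden-section search over a log-spaced
    bandwidth range around a rule-of-thumb pilot.  When no interior
    minimum exists (the score decreases toward a range edge, as happens
    for heavily duplicated data), the pilot bandwidth is returned with
    a warning.
    """
    from scipy.optimize import minimize_scalar

    pts = np.asarray(points_mm, dtype=float)
    n_all = len(pts)
    if n_all < 2:
        raise ValueError("bandwidth selection requires at least 2 points")
    # order-invariant deterministic subsample for the pairwise sums
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    if n_all > max_points:
        pts = pts[np.linspace(0, n_all - 1, max_points).astype(int)]
    n = len(pts)
    d = pts[:, None, :] - pts[None, :, :]
    sq = (d * d).sum(axis=-1)

    sigma = float(np.mean(pts.std(axis=0, ddof=1)))
    pilot = max(sigma, 1e-6) * n ** (-1.0 / 6.0)  # Scott's rule, 2-D
    lo, hi = math.log(pilot / 10.0), math.log(pilot * 10.0)
    res = minimize_scalar(
        lambda u: _lscv_score(sq, n, math.exp(u)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    u = float(res.x)
    if not res.success or u - lo < 1e-3 or hi - u < 1e-3:
        warnings.warn(
            "LSCV found no interior bandwidth minimum; falling back to the "
            f"rule-of-thumb bandwidth {pilot:.3g} mm",
            RuntimeWarning,
        )
        return pilot
    return math.exp(u)


def occupancy_kde(
    trajs: Trajectory | Sequence[Trajectory],
    field: FieldGeometry,
    cell_mm: float = 1.0,
    bandwidth_mm: Optional[float] = None,
) -> OccupancyGrid:
    """Kernel-density occupancy map over the arena, 1-mm cells by default.

    Positions from all trajectories are pooled, smoothed with an
    isotropic Gaussian kernel (bandwidth chosen by least-squares
    cross-validation unless given), rasterized at the cell centers,
    masked to the arena, and renormalized to total mass 1.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if len(trajs) == 0:
        raise ValueError("occupancy_kde requires at least one trajectory")
    if not field.bounded:
        raise ValueError("occupancy_kde requires a bounded field")
    pts_units = np.concatenate([t.positions for t in trajs], axis=0)
    pts = pts_units * MM_PER_UNIT
    # canonical order so the result is independent of trajectory ordering
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    if bandwidth_mm is None:
        bandwidth_mm = lscv_bandwidth(pts)

    xmin, xmax, ymin, ymax = (v * MM_PER_UNIT for v in field.bounding_box())
    x_centers = np.arange(xmin + cell_mm / 2, xmax, cell_mm)
    y_centers = np.arange(ymin + cell_mm / 2, ymax, cell_mm)
    gx, gy = np.meshgrid(x_centers, y_centers)  # (ny, nx)

    h = bandwidth_mm
    dens = np.zeros(gx.shape)
    # chunk over grid rows to bound memory
    for iy in range(gx.shape[0]):
        dx = gx[iy][:, None] - pts[None, :, 0]
        dy = gy[iy][:, None] - pts[None, :, 1]
        dens[iy] = _gauss2(dx * dx + dy * dy, h).mean(axis=1)

    inside = np.array(
        [
            [field.contains(x / MM_PER_UNIT, y / MM_PER_UNIT) for x in x_centers]
            for y in y_centers
        ]
    )
    dens = np.where(inside, dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("no density mass inside the field")
    return OccupancyGrid(
        x_centers=x_centers,
        y_centers=y_centers,
        density=dens / total,
        cell_mm=cell_mm,
        bandwidth_mm=bandwidth_mm,
    )
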