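"""Synthetic inputs: group parameter presets and emulated tracked data.

Three experimental groups are covered — intact animals, regenerating
head fragments, and headless bodies.  Each preset carries the measured
wigwag statistics (normal turn-angle mean/SD in radians; lognormal
inter-turn interval location/scale in log-seconds) together with the
sample sizes behind them.  All three groups turn with SD near 0.3 rad;
they differ mainly in how often they turn (headless animals pause far
longer between wigwags).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .arena import FieldGeometry, UNITS_PER_MM
from .simulator import Trajectory, WigwagParams, simulate


@dataclass(frozen=True)
class GroupPreset:
    """Measured wigwag parameters of one experimental group."""

    group: str
    params: WigwagParams
    n_angles: int
    n_animals: int


_PRESETS = {
    "intact": GroupPreset(
        group="intact",
        params=WigwagParams(
            angle_mean=-0.01, angle_sd=0.34, interval_logmean=0.14, interval_logsd=0.48
        ),
        n_angles=196,
        n_animals=15,
    ),
    "head_fragment": GroupPreset(
        group="head_fragment",
        params=WigwagParams(
            angle_mean=-0.07, angle_sd=0.36, interval_logmean=0.45, interval_logsd=0.40
        ),
        n_angles=69,
        n_animals=11,
    ),
    "headless": GroupPreset(
        group="headless",
        params=WigwagParams(
            angle_mean=0.01, angle_sd=0.32, interval_logmean=1.0, interval_logsd=0.59
        ),
        n_angles=101,
        n_animals=14,
    ),
}

GROUPS = tuple(_PRESETS)


def preset_params(group: str) -> GroupPreset:
    """Measured parameter preset for a group (intact / head_fragment / headless)."""
    try:
        return _PRESETS[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; choose from {GROUPS}") from None


def sample_wigwag(
    params: WigwagParams,
    n_angles: int,
    n_intervals: int,
    seed: int | np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw raw wigwag angles (rad) and intervals (s) from the generators."""
    if n_angles < 1 or n_intervals < 1:
        raise ValueError("sample sizes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = rng.normal(params.angle_mean, params.angle_sd, size=n_angles)
    intervals = rng.lognormal(params.interval_logmean, params.interval_logsd, size=n_intervals)
    return angles, intervals


def synth_tracked_trajectory(
    params: WigwagParams,
    field: FieldGeometry,
    duration_s: float,
    noise_sd_mm: float,
    seed: int,
    start: Optional[Tuple[float, float]] = None,
    start_theta: Optional[float] = None,
) -> Trajectory:
    """Emulate a video-tracked trajectory.

    Runs the simulator, then adds independent isotropic Gaussian jitter
    of ``noise_sd_mm`` (per coordinate) to every position — a stand-in
    for tracking error — and strips the event log, as a tracker only
    reports positions.  ``noise_sd_mm = 0`` reproduces ``simulate``
    bit-exactly for the same seed.
    """
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    clean = simulate(params, field, duration_s, rng, start=start, start_theta=start_theta)
    positions = clean.positions
    if noise_sd_mm > 0:
        jitter = rng.normal(0.0, noise_sd_mm * UNITS_PER_MM, size=positions.shape)
        positions = positions + jitter
    return Trajectory(times=clean.times, positions=positions, field=field, event_log=[])
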