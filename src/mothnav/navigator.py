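"""Moth-inspired surge-and-cast navigator driven by the puff crossing time.

The navigator is a point agent at constant ground speed that senses only a
binary odor signal (concentration above threshold) and the instantaneous wind
vector at its own position.  Its state machine:

``WAITING``
    stationary until the first detection.
``IN_PUFF``
    while the signal is on, fly upwind (180 degrees to the instantaneous
    wind) and time the contiguous detection interval; at signal loss, that
    interval is recorded as the puff crossing time ``t_c``.
``SURGE``
    continue upwind for ``t_c``; a new detection restarts the measurement.
``CAST``
    counter-turning: alternate legs of duration ``t_c`` at a fixed angle
    drawn once per casting cycle, uniformly in [alpha_min, alpha_max]
    (default 30-120 degrees), to either side of the instantaneous upwind
    direction; any detection returns to ``IN_PUFF``.

Because the crossing time scales with the size of the last puff, the surge
length and the casting width adapt to the local plume geometry without
memory or learning.  The ``internal_counter`` strategy variant replaces the
measured ``t_c`` with a fixed duration ``tau`` in both the surge and the cast
legs; it is the non-adaptive baseline.

This module is the single-step reference implementation; the vectorized
flight loop used by the Monte-Carlo harness lives in ``mothnav._kernels``
and follows the same transition rules.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Mode",
    "NavigatorParams",
    "FlierState",
    "step",
    "measure_crossing_time",
]


class Mode(enum.IntEnum):
    WAITING = 0
    IN_PUFF = 1
    SURGE = 2
    CAST = 3


@dataclass(frozen=True)
class NavigatorParams:
    """Navigator parameters.

    Parameters
    ----------
    ground_speed : float
        Constant ground speed (m/s), > 0; 0.3 by default.
    alpha_min_deg, alpha_max_deg : float
        Counter-turn angle range relative to upwind (degrees),
        0 < alpha_min <= alpha_max < 180.
    strategy : str
        'crossing_time' (surge/cast legs last the measured t_c) or
        'internal_counter' (fixed leg duration tau).
    internal_counter_tau_s : float
        Fixed leg duration for the baseline strategy (s), > 0.
    surge_timer_origin : str
        'exit' (default): the surge countdown starts when the puff is lost,
        so time inside the puff is not counted against the surge budget.
        'entry': the budget is counted from puff entry; since the crossing
        itself consumes exactly t_c, the post-exit surge vanishes and
        casting starts immediately.
    success_radius_m : float
        Radius R around the source defining a successful crossing (m).
    """

    ground_speed: float = 0.3
    alpha_min_deg: float = 30.0
    alpha_max_deg: float = 120.0
    strategy: str = "crossing_time"
    internal_counter_tau_s: float = 1.0
    surge_timer_origin: str = "exit"
    success_radius_m: float = 0.25

    def __post_init__(self) -> None:
        if not self.ground_speed > 0:
            raise ValueError("navigator.ground_speed must be > 0")
        if not 0 < self.alpha_min_deg <= self.alpha_max_deg < 180:
            raise ValueError(
                "navigator angles must satisfy 0 < alpha_min_deg <= alpha_max_deg < 180"
            )
        if self.strategy not in ("crossing_time", "internal_counter"):
            raise ValueError("navigator.strategy must be 'crossing_time' or 'internal_counter'")
        if self.strategy == "internal_counter" and not self.internal_counter_tau_s > 0:
            raise ValueError("navigator.internal_counter_tau_s must be > 0")
        if self.surge_timer_origin not in ("exit", "entry"):
            raise ValueError("navigator.surge_timer_origin must be 'exit' or 'entry'")


@dataclass(frozen=True)
class FlierState:
    """Navigator state between steps."""

    position: tuple[float, float]
    mode: Mode = Mode.WAITING
    t_c_last: float = 0.0
    time_in_mode: float = 0.0
    cast_angle_deg: float = 0.0
    cast_side: int = 1
    n_detections: int = 0
    n_search_cycles: int = 0
    n_counter_turns: int = 0
    clock: float = 0.0


def _leg_duration(state_tc: float, params: NavigatorParams) -> float:
    if params.strategy == "internal_counter":
        return params.internal_counter_tau_s
    return state_tc


def _heading(mode: Mode, wind, cast_angle_deg: float, cast_side: int) -> np.ndarray:
    u, v = float(wind[0]), float(wind[1])
    wmag = math.hypot(u, v)
    if math.isnan(wmag):
        raise FloatingPointError("NaN wind sample")
    if wmag < 1e-12:
        ux, uy = -1.0, 0.0  # degenerate calm: treat upwind as -x
    else:
        ux, uy = -u / wmag, -v / wmag
    if mode == Mode.CAST:
        theta = math.radians(cast_angle_deg) * cast_side
        c, s = math.cos(theta), math.sin(theta)
        return np.array([c * ux - s * uy, s * ux + c * uy])
    return np.array([ux, uy])


def step(
    state: FlierState,
    detected: bool,
    wind,
    dt: float,
    params: NavigatorParams,
    rng: np.random.Generator,
) -> FlierState:
    """Advance the navigator by one time step.

    ``detected`` is the binary odor signal at the current position and
    ``wind`` the instantaneous wind vector there.  The returned state has the
    position moved by ``ground_speed * dt`` along the mode's heading (or
    unchanged in WAITING).  Detection is sensed at the start of the step; the
    contiguous-detection stopwatch counts each detected step as ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")

    mode = state.mode
    time_in_mode = state.time_in_mode
    t_c = state.t_c_last
    cast_angle = state.cast_angle_deg
    side = state.cast_side
    n_det = state.n_detections
    n_cycles = state.n_search_cycles
    n_turns = state.n_counter_turns

    if mode == Mode.WAITING:
        if not detected:
            return replace(state, clock=state.clock + dt)
        mode, time_in_mode = Mode.IN_PUFF, dt
        n_det += 1
    elif mode == Mode.IN_PUFF:
        if detected:
            time_in_mode += dt
        else:
            t_c = time_in_mode  # completed crossing
            surge_budget = 0.0 if params.surge_timer_origin == "entry" else _leg_duration(t_c, params)
            if surge_budget <= 1e-12:
                mode = Mode.CAST
                cast_angle = float(rng.uniform(params.alpha_min_deg, params.alpha_max_deg))
                side = 1 if rng.random() < 0.5 else -1
                n_cycles += 1
                time_in_mode = dt
            else:
                mode, time_in_mode = Mode.SURGE, dt
    elif mode == Mode.SURGE:
        if detected:
            mode, time_in_mode = Mode.IN_PUFF, dt
            n_det += 1
        elif time_in_mode >= _leg_duration(t_c, params) - 1e-12:
            mode = Mode.CAST
            cast_angle = float(rng.uniform(params.alpha_min_deg, params.alpha_max_deg))
            side = 1 if rng.random() < 0.5 else -1
            n_cycles += 1
            time_in_mode = dt
        else:
            time_in_mode += dt
    else:  # CAST
        if detected:
            mode, time_in_mode = Mode.IN_PUFF, dt
            n_det += 1
        elif time_in_mode >= _leg_duration(t_c, params) - 1e-12:
            side = -side
            n_turns += 1
            time_in_mode = dt
        else:
            time_in_mode += dt

    heading = _heading(mode, wind, cast_angle, side)
    x, y = state.position
    new_pos = (
        x + params.ground_speed * dt * float(heading[0]),
        y + params.ground_speed * dt * float(heading[1]),
    )
    return FlierState(
        position=new_pos,
        mode=mode,
        t_c_last=t_c,
        time_in_mode=time_in_mode,
        cast_angle_deg=cast_angle,
        cast_side=side,
        n_detections=n_det,
        n_search_cycles=n_cycles,
        n_counter_turns=n_turns,
        clock=state.clock + dt,
    )


def measure_crossing_time(detections, dt: float) -> float:
    """Crossing time t_c of the last completed contiguous detection run.

    ``detections`` is a boolean series sampled at resolution ``dt``.  The
    last run must have ended (the series must not end inside a detection),
    otherwise no completed crossing exists and a ValueError is raised.
    """
    det = np.asarray(detections, dtype=bool)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if det.size == 0 or det[-1]:
        raise ValueError("no completed detection run in the series")
    # lengths of runs of True
    padded = np.concatenate([[False], det, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    if len(starts) == 0:
        raise ValueError("no completed detection run in the series")
    return float((ends[-1] - starts[-1]) * dt)
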