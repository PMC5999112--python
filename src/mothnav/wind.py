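"""Stochastic two-dimensional wind model.

The instantaneous wind at any point is a sum of processes separated by time
scale::

    u(x, y, t) = U + U_g(t) + u'(x, y, t)      (streamwise)
    v(x, y, t) = V_m(t) + v'(x, y, t)          (cross-stream)

``U``
    constant streamwise mean wind speed; the cross-stream mean is zero.
``U_g``
    gusts: intermittent piecewise-constant steps of the mean speed, a few per
    run, each held for ~10 s, with amplitude up to +-50% of ``U``.
``V_m``
    meandering: a slow (~100 s period) sinusoidal modulation of the wind
    direction, identical everywhere in the field.
``u', v'``
    turbulent fluctuations: zero-mean i.i.d. Gaussian draws, redrawn at every
    call (every position and time step), with the same rms in both components.
    The governing parameter is the turbulence intensity ``TI = u'_rms / U``.

Fluctuations are deliberately independent of the local wind value, so
enabling gusts or meandering does not change the fluctuation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WindModel",
    "GustSchedule",
    "realize_gusts",
    "gust_offset",
    "meander_velocity",
    "sample_wind",
]


@dataclass(frozen=True)
class WindModel:
    """Parameters of the stochastic wind process.

    Parameters
    ----------
    u_mean : float
        Streamwise mean wind speed U (m/s), > 0.
    turbulence_intensity : float
        Ratio of fluctuation rms to mean wind, u'_rms / U (dimensionless).
    gust_enabled : bool
        Whether gust events occur.
    gust_amplitude_frac : float
        Maximum |U_g| / U, in [0, 0.5].
    gust_hold_s : float
        Duration of one gust step (s), order of 10 s.
    gust_rate_per_run : float
        Expected number of gust events per simulation run.
    meander_enabled : bool
        Whether the cross-stream meander modulation is active.
    meander_amplitude : float
        Peak |V_m| / U (dimensionless).
    meander_period_s : float
        Meander modulation period (s), order of 100 s.
    """

    u_mean: float = 1.0
    turbulence_intensity: float = 0.15
    gust_enabled: bool = False
    gust_amplitude_frac: float = 0.5
    gust_hold_s: float = 10.0
    gust_rate_per_run: float = 3.0
    meander_enabled: bool = False
    meander_amplitude: float = 0.2
    meander_period_s: float = 100.0

    def __post_init__(self) -> None:
        if not self.u_mean > 0:
            raise ValueError("wind.u_mean must be > 0")
        if self.turbulence_intensity < 0:
            raise ValueError("wind.turbulence_intensity must be >= 0")
        if not 0.0 <= self.gust_amplitude_frac <= 0.5:
            raise ValueError("wind.gust.amplitude_frac must be in [0, 0.5]")
        if self.gust_hold_s <= 0:
            raise ValueError("wind.gust.hold_s must be > 0")
        if self.gust_rate_per_run < 0:
            raise ValueError("wind.gust.rate_per_run must be >= 0")
        if self.meander_amplitude < 0:
            raise ValueError("wind.meander.amplitude must be >= 0")
        if not self.meander_period_s > 0:
            raise ValueError("wind.meander.period_s must be > 0")

    @property
    def sigma_u(self) -> float:
        """Fluctuation rms (m/s) of each component."""
        return self.turbulence_intensity * self.u_mean


@dataclass(frozen=True)
class GustSchedule:
    """One realized gust event schedule: onset times and amplitudes (m/s)."""

    starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    hold_s: float = 10.0

    def __len__(self) -> int:
        return len(self.starts)


def realize_gusts(model: WindModel, duration_s: float, rng: np.random.Generator) -> GustSchedule:
    """Draw one gust event schedule for a run of length ``duration_s``.

    The number of events is Poisson with mean ``gust_rate_per_run``, onsets are
    uniform over the run, and each amplitude is drawn uniformly in
    ``+- gust_amplitude_frac * u_mean``.  Overlapping events superpose.
    """
    if not model.gust_enabled or model.gust_rate_per_run == 0:
        return GustSchedule(hold_s=model.gust_hold_s)
    n = int(rng.poisson(model.gust_rate_per_run))
    starts = np.sort(rng.uniform(0.0, duration_s, size=n))
    amp = model.gust_amplitude_frac * model.u_mean
    amplitudes = rng.uniform(-amp, amp, size=n)
    return GustSchedule(starts=starts, amplitudes=amplitudes, hold_s=model.gust_hold_s)


def gust_offset(t, schedule: GustSchedule):
    """Piecewise-constant gust speed offset U_g(t) in m/s (scalar or array t)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for s, a in zip(schedule.starts, schedule.amplitudes):
        out += np.where((t >= s) & (t < s + schedule.hold_s), a, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def meander_velocity(t, model: WindModel):
    """Cross-stream meander velocity V_m(t) = a * U * sin(2 pi t / P) in m/s."""
    if not model.meander_enabled:
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    v = model.meander_amplitude * model.u_mean * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / model.meander_period_s)
    return float(v) if np.ndim(t) == 0 else v


def sample_wind(
    position,
    t: float,
    model: WindModel,
    rng: np.random.Generator,
    gusts: GustSchedule | None = None,
) -> np.ndarray:
    """Instantaneous wind vector (u, v) in m/s at ``position`` and time ``t``.

    ``position`` is accepted for interface symmetry: the mean terms are
    spatially uniform and the fluctuations are i.i.d. in space, so the value
    does not depend on it.  A fresh fluctuation pair is drawn on every call.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if gusts is None:
        gusts = GustSchedule(hold_s=model.gust_hold_s)
    ug = gust_offset(t, gusts)
    vm = meander_velocity(t, model)
    fluct = model.sigma_u * rng.standard_normal(2)
    return np.array([model.u_mean + ug + fluct[0], vm + fluct[1]])
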