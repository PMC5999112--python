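"""Lagrangian Gaussian-puff plume from a pulsating point source.

A source at the origin releases one instantaneous puff of odor mass ``m``
every ``T`` seconds.  Puff centers are advected passively by the instantaneous
wind; each puff grows with its age ``a = t - t_i`` as

    sigma_{h,z}(a) = A_{h,z} * a ** B_{h,z},        B ~= 1,

and contributes a normalized trivariate Gaussian to the concentration field::

    C(r, t) = sum_i  m / ((2 pi)^(3/2) sigma_h^2 sigma_z)
              * exp(-|r - r_p,i|^2 / (2 sigma_h^2)) * (vertical factor)

evaluated on the flight plane z = z0, where the vertical factor is 1 (the
navigator flies at the release height).  The growth coefficient scales with
the turbulence intensity, A = growth_coupling * TI * U, so that more
turbulent flow spreads puffs faster and dilutes them sooner.

A navigator perceives only the binary signal ``C >= C*`` where ``C*`` is the
lowest detectable concentration.  ``calibrate_threshold`` fixes ``C*`` from a
geometric condition (detectable puff radius at a reference downwind
distance), which keeps the detectable patch geometry comparable across
turbulence intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .wind import GustSchedule, WindModel, gust_offset, meander_velocity, realize_gusts

__all__ = [
    "PlumeModel",
    "Puffs",
    "release_schedule",
    "puff_sigma",
    "peak_concentration",
    "concentration_at",
    "detect",
    "detectable_radius",
    "detectable_age_limit",
    "calibrate_threshold",
    "growth_rate_from_ti",
    "advect_puffs",
    "PlumeField",
    "build_field",
]

#: (2 pi)^(3/2), the trivariate Gaussian normalization constant.
TWO_PI_32 = (2.0 * math.pi) ** 1.5


@dataclass(frozen=True)
class PlumeModel:
    """Parameters of the pulsating-source puff plume.

    Parameters
    ----------
    pulse_interval_s : float
        Time T between instantaneous releases (s), > 0.
    mass_per_pulse : float
        Odor mass m released per pulse (arbitrary mass units), > 0.
    a_h, a_z : float
        Horizontal / vertical growth-rate coefficients (m/s), > 0 in live
        configurations (0 is tolerated for degenerate test fixtures together
        with the sigma floor).
    b_h, b_z : float
        Growth exponents (dimensionless); 1 by default.
    z0_m : float
        Release height above ground (m).  The navigator flies in this plane.
    threshold : float
        Lowest detectable concentration C* (mass / m^3), > 0.
    sigma_floor_m : float
        Minimal puff size (m); guards the age-zero singularity.
    vertical_term : str
        'standard' evaluates the Gaussian vertical factor at the flight plane
        z = z0 (factor 1); 'printed' applies exp(-z0^2 / sigma_z^2) instead,
        an alternative reading kept for fidelity checks.
    """

    pulse_interval_s: float = 1.0
    mass_per_pulse: float = 1.0
    a_h: float = 0.0105
    a_z: float = 0.0105
    b_h: float = 1.0
    b_z: float = 1.0
    z0_m: float = 0.0
    threshold: float = 1.0
    sigma_floor_m: float = 0.125
    vertical_term: str = "standard"

    def __post_init__(self) -> None:
        if not self.pulse_interval_s > 0:
            raise ValueError("plume.pulse_interval_s must be > 0")
        if not self.mass_per_pulse > 0:
            raise ValueError("plume.mass_per_pulse must be > 0")
        if self.a_h < 0 or self.a_z < 0:
            raise ValueError("plume.a_h and plume.a_z must be >= 0")
        if self.b_h < 0 or self.b_z < 0:
            raise ValueError("plume.b_h and plume.b_z must be >= 0")
        if not self.threshold > 0:
            raise ValueError("plume.threshold must be > 0")
        if not self.sigma_floor_m > 0:
            raise ValueError("plume.sigma_floor_m must be > 0")
        if self.vertical_term not in ("standard", "printed"):
            raise ValueError("plume.vertical_term must be 'standard' or 'printed'")


@dataclass
class Puffs:
    """A set of released puffs: release times (s) and center positions (m).

    ``centers[i]`` is the (x, y) center of the puff released at
    ``release_times[i]``.  Puffs not yet released at the evaluation time are
    masked out by the operations (the Heaviside factor of the model).
    """

    release_times: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.release_times = np.asarray(self.release_times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape != (len(self.release_times), 2):
            raise ValueError("centers must have shape (n_puffs, 2)")

    def __len__(self) -> int:
        return len(self.release_times)


def growth_rate_from_ti(ti: float, u_mean: float, coupling: float) -> float:
    """Puff growth rate A (m/s) from turbulence intensity: A = c * TI * U."""
    return coupling * ti * u_mean


def release_schedule(t_end: float, model: PlumeModel) -> np.ndarray:
    """Release times {0, T, 2T, ...} <= t_end for the pulsating source."""
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    n = int(math.floor(t_end / model.pulse_interval_s)) + 1
    return np.arange(n) * model.pulse_interval_s


def puff_sigma(age, model: PlumeModel):
    """Puff sizes (sigma_h, sigma_z) in m at the given age(s).

    sigma = max(A * age ** B, sigma_floor); the floor guards the age-zero
    singularity of the concentration prefactor.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("puff queried before its release (age < 0)")
    sh = np.maximum(model.a_h * age**model.b_h, model.sigma_floor_m)
    sz = np.maximum(model.a_z * age**model.b_z, model.sigma_floor_m)
    if age.ndim == 0:
        return float(sh), float(sz)
    return sh, sz


def _vertical_factor(sz, model: PlumeModel):
    if model.vertical_term == "printed":
        return np.exp(-(model.z0_m**2) / sz**2)
    return np.ones_like(np.asarray(sz, dtype=float)) if np.ndim(sz) else 1.0


def peak_concentration(age, model: PlumeModel):
    """Concentration at a puff's center at the given age(s) (mass / m^3)."""
    sh, sz = puff_sigma(age, model)
    peak = model.mass_per_pulse / (TWO_PI_32 * np.asarray(sh) ** 2 * np.asarray(sz))
    peak = peak * _vertical_factor(sz, model)
    return float(peak) if np.ndim(age) == 0 else peak


def concentration_at(point, t: float, puffs: Puffs, model: PlumeModel, z: float | None = None) -> float:
    """Total concentration (mass / m^3) at ``point`` at time ``t``.

    Sums the Gaussian contributions of all puffs released at or before ``t``
    (unreleased puffs do not exist yet).  ``puffs.centers`` must have been
    advected to time ``t`` by the caller.  By default the field is evaluated
    on the flight plane ``z = z0``; passing ``z`` evaluates the full
    trivariate Gaussian at that height (standard vertical term only).
    """
    point = np.asarray(point, dtype=float)
    ages = t - puffs.release_times
    live = ages >= 0
    if not np.any(live):
        return 0.0
    ages = ages[live]
    centers = puffs.centers[live]
    sh, sz = puff_sigma(ages, model)
    sh = np.atleast_1d(sh)
    sz = np.atleast_1d(sz)
    if z is None:
        vert = np.atleast_1d(_vertical_factor(sz, model))
    else:
        if model.vertical_term != "standard":
            raise ValueError("explicit z evaluation requires the standard vertical term")
        vert = np.exp(-((z - model.z0_m) ** 2) / (2.0 * sz**2))
    d2 = np.sum((centers - point) ** 2, axis=1)
    contrib = (
        model.mass_per_pulse
        / (TWO_PI_32 * sh**2 * sz)
        * np.exp(-d2 / (2.0 * sh**2))
        * vert
    )
    return float(np.sum(contrib))


def detect(point, t: float, puffs: Puffs, model: PlumeModel) -> bool:
    """Binary odor detection: concentration at ``point`` >= threshold C*."""
    return concentration_at(point, t, puffs, model) >= model.threshold


def detectable_radius(age: float, model: PlumeModel) -> float:
    """Radius (m) of the C* isoline of a single puff at the given age.

    rho = sigma_h * sqrt(2 ln(C_peak / C*)) when the peak is detectable,
    else NaN ("undetectable").  Used for pruning and as a test oracle.
    """
    peak = peak_concentration(age, model)
    if peak < model.threshold:
        return float("nan")
    sh, _ = puff_sigma(age, model)
    return float(sh * math.sqrt(2.0 * math.log(peak / model.threshold)))


def detectable_age_limit(model: PlumeModel, age_cap: float = 1.0e5) -> float:
    """Age (s) beyond which a single puff's peak falls below C*.

    With B = 1 the peak decays as age^-3, so once undetectable a puff never
    becomes detectable again.  Returns ``inf`` if the peak is still
    detectable at ``age_cap``.
    """
    if peak_concentration(age_cap, model) >= model.threshold:
        return float("inf")
    lo, hi = 0.0, age_cap
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if peak_concentration(mid, model) >= model.threshold:
            lo = mid
        else:
            hi = mid
    return hi


def calibrate_threshold(
    model: PlumeModel,
    u_mean: float,
    x_ref_m: float = 10.0,
    rho_ref_m: float = 0.2,
) -> float:
    """Detection threshold C* from a geometric reference condition.

    Chooses C* so that a puff arriving at the reference downwind distance
    ``x_ref_m`` (age x_ref / U under pure mean-wind advection) has a
    detectable radius of ``rho_ref_m``.  Pinning the patch size at a fixed
    distance keeps the detectable plume geometry comparable across turbulence
    intensities, whose growth rates A differ.
    """
    age_ref = x_ref_m / u_mean
    sh, _ = puff_sigma(age_ref, model)
    peak = peak_concentration(age_ref, model)
    return float(peak * math.exp(-(rho_ref_m**2) / (2.0 * sh**2)))


def advect_puffs(
    puffs: Puffs,
    wind: WindModel,
    t: float,
    dt: float,
    rng: np.random.Generator,
    gusts: GustSchedule | None = None,
) -> Puffs:
    """Advance released puff centers by one step: r(t+dt) = r(t) + U[r, t] dt.

    Each released puff sees the shared mean terms (U, U_g, V_m) plus its own
    independent fluctuation draw (fluctuations are uncorrelated between
    locations).  Puffs not yet released stay at the origin.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if gusts is None:
        gusts = GustSchedule(hold_s=wind.gust_hold_s)
    live = puffs.release_times <= t
    centers = puffs.centers.copy()
    n_live = int(np.count_nonzero(live))
    if n_live:
        ug = gust_offset(t, gusts)
        vm = meander_velocity(t, wind)
        fluct = wind.sigma_u * rng.standard_normal((n_live, 2))
        vel = np.column_stack(
            [wind.u_mean + ug + fluct[:, 0], vm + fluct[:, 1]]
        )
        centers[live] += vel * dt
    return Puffs(release_times=puffs.release_times, centers=centers)


# ---------------------------------------------------------------------------
# Precomputed plume field
# ---------------------------------------------------------------------------

@dataclass
class PlumeField:
    """One realized plume: puff center tracks on a fixed time grid.

    The field is simulated once per realization and shared by all flights in
    it (the paper's design of 10 fields x 100 flights).  ``traj_x[i, a]`` is
    the x position of puff ``i`` at age step ``a``; a puff is live while
    ``0 <= a < lengths[i]`` (it is pruned once its center passes the
    downstream limit or its peak concentration falls below C*).
    """

    wind: WindModel
    plume: PlumeModel
    gusts: GustSchedule
    dt: float
    duration_s: float
    pulse_steps: int
    release_steps: np.ndarray
    traj_x: np.ndarray
    traj_y: np.ndarray
    lengths: np.ndarray

    @property
    def n_puffs(self) -> int:
        return len(self.release_steps)

    def live_puffs(self, t: float) -> Puffs:
        """Released, un-pruned puffs at time ``t`` (nearest grid step)."""
        k = int(round(t / self.dt))
        ages = k - self.release_steps
        live = (ages >= 0) & (ages < self.lengths)
        idx = np.nonzero(live)[0]
        centers = np.column_stack(
            [self.traj_x[idx, ages[idx]], self.traj_y[idx, ages[idx]]]
        )
        return Puffs(
            release_times=self.release_steps[idx] * self.dt,
            centers=centers.reshape(-1, 2),
        )

    def concentration(self, point, t: float) -> float:
        return concentration_at(point, t, self.live_puffs(t), self.plume)

    def detect(self, point, t: float) -> bool:
        return self.concentration(point, t) >= self.plume.threshold


def build_field(
    wind: WindModel,
    plume: PlumeModel,
    duration_s: float,
    dt: float,
    x_prune: float,
    rng: np.random.Generator,
) -> PlumeField:
    """Simulate one plume realization over ``[0, duration_s]``.

    Puff velocities do not depend on puff position (uniform mean terms,
    spatially i.i.d. fluctuations), so each track is a cumulative sum of
    per-step velocity draws.  Tracks are truncated where the center passes
    ``x_prune`` or the age exceeds the detectability limit.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pulse_steps = int(round(plume.pulse_interval_s / dt))
    if abs(pulse_steps * dt - plume.pulse_interval_s) > 1e-9 or pulse_steps < 1:
        raise ValueError("plume.pulse_interval_s must be a positive multiple of dt")

    gusts = realize_gusts(wind, duration_s, rng)

    release_times = release_schedule(duration_s, plume)
    release_steps = np.round(release_times / dt).astype(np.int64)
    n = len(release_steps)

    a_max = detectable_age_limit(plume)
    # generous travel-time cap: even against a sustained -50% gust the center
    # clears the pruning boundary well within 3 x_prune / U
    t_cap = 3.0 * x_prune / wind.u_mean
    max_len = int(math.ceil(min(a_max, t_cap) / dt)) + 2

    ages = np.arange(max_len - 1) * dt  # velocity sampled at age steps 0..max_len-2
    t_abs = release_times[:, None] + ages[None, :]
    ug = gust_offset(t_abs, gusts)
    vm = meander_velocity(t_abs, wind) if wind.meander_enabled else 0.0
    sig = wind.sigma_u
    vx = wind.u_mean + ug + sig * rng.standard_normal((n, max_len - 1))
    vy = vm + sig * rng.standard_normal((n, max_len - 1))

    traj_x = np.empty((n, max_len))
    traj_y = np.empty((n, max_len))
    traj_x[:, 0] = 0.0
    traj_y[:, 0] = 0.0
    np.cumsum(vx * dt, axis=1, out=traj_x[:, 1:])
    np.cumsum(vy * dt, axis=1, out=traj_y[:, 1:])

    # truncate at the pruning boundary
    past = traj_x > x_prune
    lengths = np.where(past.any(axis=1), past.argmax(axis=1), max_len).astype(np.int64)
    # puffs released near the end of the run have short tracks anyway; clip
    # to the simulated horizon
    horizon = int(round(duration_s / dt)) + 1
    lengths = np.minimum(lengths, np.maximum(horizon - release_steps, 0))

    return PlumeField(
        wind=wind,
        plume=plume,
        gusts=gusts,
        dt=dt,
        duration_s=duration_s,
        pulse_steps=pulse_steps,
        release_steps=release_steps,
        traj_x=traj_x,
        traj_y=traj_y,
        lengths=lengths,
    )


def with_threshold(model: PlumeModel, threshold: float) -> PlumeModel:
    """Copy of ``model`` with a new detection threshold."""
    return replace(model, threshold=threshold)
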