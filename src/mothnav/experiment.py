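"""Monte-Carlo harness: fields, flights, success classification and metrics.

For each flow condition the harness builds ``n_fields`` independent plume
realizations and runs ``n_flights_per_field`` navigation flights per field
(the default 10 x 100 gives 1000 flights per turbulence-intensity level).
A flight starts when the flier, placed at rest at a random downwind position,
first detects a passing puff; it ends when the flier crosses the source line
x = 0 (the crossing's transverse offset against the radius R classifies
success), escapes downstream, or times out.  Fliers that never detect
anything are excluded from the statistics entirely.

Per-flight metrics (over successful flights): total flight time (first
detection to crossing), accumulated casting (search) time, number of search
cycles (surge-to-cast transitions) and counter-turns, trajectory length, and
the dimensionless lateral deviation of the path from its straight chord.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .config import (
    SimulationConfig,
    field_seedseq,
    flight_seedseq,
    kernel_seed,
    resolve_condition,
    spin_up_time,
)
from .navigator import NavigatorParams
from .plume import PlumeField, build_field

__all__ = [
    "FlightRecord",
    "ExperimentSummary",
    "run_flight",
    "classify_success",
    "compute_lateral_deviation",
    "run_condition",
    "run_experiment",
    "compare_strategies",
    "summarize",
]

_STATUS_NAMES = {
    _kernels.STATUS_CROSSED: "crossed",
    _kernels.STATUS_ESCAPED: "escaped",
    _kernels.STATUS_TIMEOUT: "timeout",
    _kernels.STATUS_NEVER_STARTED: "never_started",
}


@dataclass
class FlightRecord:
    """Outcome and metrics of one flight."""

    status: str
    start_x_m: float
    start_y_m: float
    t_start_s: float
    t_cross_s: float
    y_at_cross_m: float
    flight_time_s: float
    search_time_s: float
    n_detections: int
    n_search_cycles: int
    n_counter_turns: int
    trajectory_length_m: float
    first_tc_s: float
    lateral_deviation: float
    trajectory: np.ndarray | None = None  # columns t, x, y, mode

    @property
    def crossed(self) -> bool:
        return self.status == "crossed"

    @property
    def started(self) -> bool:
        return self.status != "never_started"


def classify_success(record: FlightRecord, radius_m: float) -> bool:
    """Crossed the source line within |y| <= R (censored flights fail)."""
    return record.crossed and abs(record.y_at_cross_m) <= radius_m


def compute_lateral_deviation(xy: np.ndarray, ground_speed: float, dt: float) -> float:
    """Path-integral lateral deviation of a sampled trajectory.

    Sum over samples of the perpendicular distance to the chord joining the
    first and last trajectory points, converted to a path integral by the
    per-sample arc length ``ground_speed * dt`` and normalized by the squared
    chord length (dimensionless).  Returns NaN for a degenerate zero-length
    chord.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return float("nan")
    chord = xy[-1] - xy[0]
    length = float(np.hypot(*chord))
    if length < 1e-12:
        return float("nan")
    rel = xy - xy[0]
    d = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / length
    return float(np.sum(d) * ground_speed * dt / length**2)


def run_flight(
    field: PlumeField,
    params: NavigatorParams,
    start_position,
    seed: int,
    dt: float,
    max_sim_time_s: float,
    t0_s: float = 0.0,
    x_escape_m: float | None = None,
    record_trajectory: bool = False,
) -> FlightRecord:
    """Run one flight against a precomputed plume field.

    The flier is placed at ``start_position`` at time ``t0_s`` (after field
    spin-up) and simulated jointly with the plume on the field's dt grid for
    at most ``max_sim_time_s``.  ``seed`` drives the flight's private random
    stream (wind fluctuations seen by the flier, cast angles and sides).
    """
    x0, y0 = float(start_position[0]), float(start_position[1])
    n_steps = int(round(max_sim_time_s / dt))
    k0 = int(round(t0_s / dt))
    if x_escape_m is None:
        x_escape_m = float(field.traj_x.max()) + 1.0

    wind = field.wind
    plume = field.plume
    out_x = np.empty(n_steps + 1)
    out_y = np.empty(n_steps + 1)
    out_mode = np.empty(n_steps + 1, dtype=np.int64)

    (
        status_code,
        t_start,
        t_cross,
        y_cross,
        flight_time,
        search_time,
        n_det,
        n_cycles,
        n_turns,
        path_length,
        first_tc,
        rec,
    ) = _kernels.run_flight_kernel(
        x0,
        y0,
        k0,
        n_steps,
        dt,
        field.pulse_steps,
        field.lengths,
        field.traj_x,
        field.traj_y,
        plume.a_h,
        plume.a_z,
        plume.b_h,
        plume.b_z,
        plume.sigma_floor_m,
        plume.mass_per_pulse,
        plume.threshold,
        plume.z0_m,
        plume.vertical_term == "printed",
        wind.u_mean,
        wind.turbulence_intensity,
        field.gusts.starts,
        field.gusts.amplitudes,
        field.gusts.hold_s,
        wind.meander_amplitude if wind.meander_enabled else 0.0,
        wind.meander_period_s,
        params.ground_speed,
        params.alpha_min_deg,
        params.alpha_max_deg,
        params.strategy == "crossing_time",
        params.internal_counter_tau_s,
        params.surge_timer_origin == "entry",
        x_escape_m,
        int(seed),
        out_x,
        out_y,
        out_mode,
    )

    status = _STATUS_NAMES[status_code]
    lateral = float("nan")
    if status == "crossed":
        start_idx = max(int(round((t_start - t0_s) / dt)), 0)
        lateral = compute_lateral_deviation(
            np.column_stack([out_x[start_idx : rec + 1], out_y[start_idx : rec + 1]]),
            params.ground_speed,
            dt,
        )

    trajectory = None
    if record_trajectory:
        times = (k0 + np.arange(rec + 1)) * dt
        trajectory = np.column_stack([times, out_x[: rec + 1], out_y[: rec + 1], out_mode[: rec + 1]])

    return FlightRecord(
        status=status,
        start_x_m=x0,
        start_y_m=y0,
        t_start_s=t_start,
        t_cross_s=t_cross,
        y_at_cross_m=y_cross,
        flight_time_s=flight_time,
        search_time_s=search_time,
        n_detections=n_det,
        n_search_cycles=n_cycles,
        n_counter_turns=n_turns,
        trajectory_length_m=path_length,
        first_tc_s=first_tc,
        lateral_deviation=lateral,
        trajectory=trajectory,
    )


def run_condition(
    cfg: SimulationConfig,
    ti: float | None = None,
    params: NavigatorParams | None = None,
) -> pd.DataFrame:
    """All flights of one condition as a per-flight DataFrame.

    The plume fields and every flight's start position and random stream are
    keyed by (master seed, TI, field index, flight index) only, so two calls
    with different navigator parameters are paired run for run.
    """
    wind, plume, nav = resolve_condition(cfg, ti)
    if params is not None:
        nav = params
    if ti is None:
        ti = cfg.wind.turbulence_intensity
    exp = cfg.experiment
    dt = exp.dt_s
    spin = spin_up_time(cfg)
    duration = spin + exp.max_sim_time_s
    x_lo, x_hi = exp.start_x_range_m
    x_prune = x_hi + exp.prune_margin_m
    x_escape = x_hi + exp.escape_margin_m

    rows = []
    for fi in range(exp.n_fields):
        frng = np.random.default_rng(field_seedseq(cfg.seed, ti, fi))
        field = build_field(wind, plume, duration, dt, x_prune, frng)
        for fj in range(exp.n_flights_per_field):
            fss = flight_seedseq(cfg.seed, ti, fi, fj)
            jrng = np.random.default_rng(fss)
            x0 = jrng.uniform(x_lo, x_hi)
            y0 = jrng.uniform(-exp.start_y_halfwidth_m, exp.start_y_halfwidth_m)
            rec = run_flight(
                field,
                nav,
                (x0, y0),
                kernel_seed(fss),
                dt,
                exp.max_sim_time_s,
                t0_s=spin,
                x_escape_m=x_escape,
            )
            row = dataclasses.asdict(rec)
            row.pop("trajectory")
            row.update(field_id=fi, flight_id=fj, ti=ti)
            rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["ti", "field_id", "flight_id", "status"]
    return df[lead + [c for c in df.columns if c not in lead]]


def run_experiment(cfg: SimulationConfig) -> "ExperimentSummary":
    """Full sweep over the configured turbulence-intensity grid."""
    flights = pd.concat(
        [run_condition(cfg, ti) for ti in cfg.experiment.ti_grid], ignore_index=True
    )
    return summarize(flights, cfg)


def compare_strategies(cfg: SimulationConfig, tau_grid) -> pd.DataFrame:
    """Success of the fixed internal-counter baseline across tau, paired
    against the crossing-time strategy (reported at tau = 0).

    Same fields, same start positions and same per-flight random streams for
    every strategy, so differences are attributable to the strategy alone.
    """
    radius = cfg.experiment.metrics_radius_m
    _, _, nav = resolve_condition(cfg)
    out = []

    def success_rate(df: pd.DataFrame) -> tuple[float, int]:
        started = df[df.status != "never_started"]
        if len(started) == 0:
            return float("nan"), 0
        ok = (started.status == "crossed") & (started.y_at_cross_m.abs() <= radius)
        return float(ok.mean()), int(len(started))

    base = run_condition(
        cfg, params=dataclasses.replace(nav, strategy="crossing_time")
    )
    rate, n = success_rate(base)
    out.append({"tau_s": 0.0, "strategy": "crossing_time", "success_rate": rate, "n_started": n})
    for tau in tau_grid:
        df = run_condition(
            cfg,
            params=dataclasses.replace(
                nav, strategy="internal_counter", internal_counter_tau_s=float(tau)
            ),
        )
        rate, n = success_rate(df)
        out.append(
            {"tau_s": float(tau), "strategy": "internal_counter", "success_rate": rate, "n_started": n}
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = [
    "flight_time_s",
    "search_time_s",
    "n_search_cycles",
    "n_counter_turns",
    "trajectory_length_m",
    "lateral_deviation",
    "first_tc_s",
]


@dataclass
class ExperimentSummary:
    """Aggregates of one experiment.

    ``success``: per (TI, R) the mean success probability over field
    replicates with its across-field standard deviation (the error-bar
    construction over 10 x 100 runs).  ``metrics``: per TI the mean and SD of
    each flight metric over successful flights at the metrics radius.
    ``flights``: the underlying per-flight table.
    """

    success: pd.DataFrame
    metrics: pd.DataFrame
    flights: pd.DataFrame

    def success_probability(self, ti: float, radius_m: float) -> float:
        s = self.success
        row = s[(np.isclose(s.ti, ti)) & (np.isclose(s.radius_m, radius_m))]
        return float(row.success_mean.iloc[0])

    def to_dict(self) -> dict:
        return {
            "success": self.success.to_dict(orient="records"),
            "metrics": self.metrics.to_dict(orient="records"),
        }


def summarize(flights: pd.DataFrame, cfg: SimulationConfig) -> ExperimentSummary:
    exp = cfg.experiment
    started = flights[flights.status != "never_started"]

    success_rows = []
    for ti, df_ti in started.groupby("ti"):
        for radius in exp.radii_m:
            per_field = df_ti.groupby("field_id").apply(
                lambda g: ((g.status == "crossed") & (g.y_at_cross_m.abs() <= radius)).mean(),
                include_groups=False,
            )
            success_rows.append(
                {
                    "ti": float(ti),
                    "radius_m": float(radius),
                    "success_mean": float(per_field.mean()),
                    "success_sd_fields": float(per_field.std(ddof=1)) if len(per_field) > 1 else 0.0,
                    "n_started": int(len(df_ti)),
                    "n_fields": int(per_field.shape[0]),
                }
            )

    metric_rows = []
    for ti, df_ti in started.groupby("ti"):
        ok = df_ti[
            (df_ti.status == "crossed") & (df_ti.y_at_cross_m.abs() <= exp.metrics_radius_m)
        ]
        row = {"ti": float(ti), "n_successful": int(len(ok))}
        for col in _METRIC_COLUMNS:
            row[f"{col}_mean"] = float(ok[col].mean()) if len(ok) else float("nan")
            row[f"{col}_sd"] = float(ok[col].std(ddof=1)) if len(ok) > 1 else float("nan")
        metric_rows.append(row)

    return ExperimentSummary(
        success=pd.DataFrame(success_rows),
        metrics=pd.DataFrame(metric_rows),
        flights=flights,
    )
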