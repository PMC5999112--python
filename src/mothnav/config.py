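"""Configuration schema, validation, seed management, manifests and fixtures.

All simulation inputs are configuration: there is no external data.  A
:class:`SimulationConfig` materializes every default; YAML or JSON files
override fields selectively and unknown keys are rejected.  Units are encoded
in the key names (``_s`` seconds, ``_m`` meters, ``_deg`` degrees; speeds in
m/s).

Randomness is organized as a seed tree: one master seed expands through
``numpy.random.SeedSequence`` spawn keys into named child streams — one per
plume field realization and one per flight — so adding flights or conditions
never perturbs existing streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .navigator import NavigatorParams
from .plume import PlumeModel, calibrate_threshold, growth_rate_from_ti
from .wind import WindModel

__all__ = [
    "GustConfig",
    "MeanderConfig",
    "WindConfig",
    "CalibrationConfig",
    "PlumeConfig",
    "NavigatorConfig",
    "ExperimentConfig",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "resolve_condition",
    "child_seedseq",
    "kernel_seed",
    "RunManifest",
    "make_manifest",
    "write_table",
    "make_fixture",
    "FIXTURE_NAMES",
]

VERSION = "0.1.0"


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class GustConfig:
    enabled: bool = False
    amplitude_frac: float = 0.5
    hold_s: float = 10.0
    rate_per_run: float = 3.0


@dataclass(frozen=True)
class MeanderConfig:
    enabled: bool = False
    amplitude: float = 0.2
    period_s: float = 100.0


@dataclass(frozen=True)
class WindConfig:
    u_mean: float = 1.0
    turbulence_intensity: float = 0.15
    gust: GustConfig = field(default_factory=GustConfig)
    meander: MeanderConfig = field(default_factory=MeanderConfig)


@dataclass(frozen=True)
class CalibrationConfig:
    """Geometric reference fixing the detection threshold.

    C* is chosen once, at the reference turbulence intensity ``ti_ref``, so
    that a puff arriving at the reference downwind distance ``x_ref_m`` has a
    detectable radius ``rho_ref_m``; the same C* is then used across the
    whole TI sweep (the sensor does not change with the weather)."""

    x_ref_m: float = 10.0
    rho_ref_m: float = 0.3
    ti_ref: float = 0.15


@dataclass(frozen=True)
class PlumeConfig:
    """Plume parameters; ``a_h``, ``a_z`` and ``threshold`` may be ``null``
    (None) in which case they are derived per condition: A = growth_coupling
    * TI * U and C* from the calibration reference."""

    pulse_interval_s: float = 1.0
    mass_per_pulse: float = 1.0
    growth_coupling: float = 0.07
    a_h: float | None = None
    a_z: float | None = None
    b_h: float = 1.0
    b_z: float = 1.0
    z0_m: float = 0.0
    threshold: float | None = None
    sigma_floor_m: float = 0.125
    vertical_term: str = "standard"
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)


@dataclass(frozen=True)
class NavigatorConfig:
    ground_speed: float = 0.3
    alpha_min_deg: float = 30.0
    alpha_max_deg: float = 120.0
    strategy: str = "crossing_time"
    internal_counter_tau_s: float = 1.0
    surge_timer_origin: str = "exit"


@dataclass(frozen=True)
class ExperimentConfig:
    n_fields: int = 10
    n_flights_per_field: int = 100
    ti_grid: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    radii_m: tuple = (0.15, 0.20, 0.25)
    metrics_radius_m: float = 0.25
    start_x_range_m: tuple = (6.0, 20.0)
    start_y_halfwidth_m: float = 0.4
    dt_s: float = 0.05
    max_sim_time_s: float = 600.0
    spin_up_s: float | None = None  # default: 1.5 * max start distance / U
    prune_margin_m: float = 4.0
    escape_margin_m: float = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 12345
    wind: WindConfig = field(default_factory=WindConfig)
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    navigator: NavigatorConfig = field(default_factory=NavigatorConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)


# ---------------------------------------------------------------------------
# Construction from nested dicts with strict key checking
# ---------------------------------------------------------------------------

def _build(cls, data: Any, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path or 'config'}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in _SECTION_TYPES
        ):
            section_cls = f.type if dataclasses.is_dataclass(f.type) else _SECTION_TYPES[f.type]
            kwargs[name] = _build(section_cls, value, sub)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


_SECTION_TYPES = {
    "GustConfig": GustConfig,
    "MeanderConfig": MeanderConfig,
    "WindConfig": WindConfig,
    "CalibrationConfig": CalibrationConfig,
    "PlumeConfig": PlumeConfig,
    "NavigatorConfig": NavigatorConfig,
    "ExperimentConfig": ExperimentConfig,
}


def config_from_dict(data: dict | None) -> SimulationConfig:
    """Build and validate a :class:`SimulationConfig` from a nested dict."""
    cfg = _build(SimulationConfig, data, "")
    validate_config(cfg)
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Fully materialized nested dict (tuples rendered as lists)."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    return clean(dataclasses.asdict(cfg))


def validate_config(cfg: SimulationConfig) -> None:
    """Range and consistency checks; raises ConfigError naming the key."""
    w, p, n, e = cfg.wind, cfg.plume, cfg.navigator, cfg.experiment
    try:
        WindModel(
            u_mean=w.u_mean,
            turbulence_intensity=w.turbulence_intensity,
            gust_enabled=w.gust.enabled,
            gust_amplitude_frac=w.gust.amplitude_frac,
            gust_hold_s=w.gust.hold_s,
            gust_rate_per_run=w.gust.rate_per_run,
            meander_enabled=w.meander.enabled,
            meander_amplitude=w.meander.amplitude,
            meander_period_s=w.meander.period_s,
        )
        NavigatorParams(
            ground_speed=n.ground_speed,
            alpha_min_deg=n.alpha_min_deg,
            alpha_max_deg=n.alpha_max_deg,
            strategy=n.strategy,
            internal_counter_tau_s=n.internal_counter_tau_s,
            surge_timer_origin=n.surge_timer_origin,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if not p.pulse_interval_s > 0:
        raise ConfigError("plume.pulse_interval_s must be > 0")
    if not p.mass_per_pulse > 0:
        raise ConfigError("plume.mass_per_pulse must be > 0")
    if p.growth_coupling <= 0:
        raise ConfigError("plume.growth_coupling must be > 0")
    if p.threshold is not None and p.threshold <= 0:
        raise ConfigError("plume.threshold must be > 0")
    if p.vertical_term not in ("standard", "printed"):
        raise ConfigError("plume.vertical_term must be 'standard' or 'printed'")
    if not p.calibration.x_ref_m > 0 or not p.calibration.rho_ref_m > 0:
        raise ConfigError("plume.calibration.{x_ref_m,rho_ref_m} must be > 0")
    if not e.dt_s > 0:
        raise ConfigError("experiment.dt_s must be > 0")
    if not e.dt_s < p.pulse_interval_s:
        raise ConfigError("experiment.dt_s must be smaller than plume.pulse_interval_s")
    pulse_steps = round(p.pulse_interval_s / e.dt_s)
    if abs(pulse_steps * e.dt_s - p.pulse_interval_s) > 1e-9:
        raise ConfigError("plume.pulse_interval_s must be an integer multiple of experiment.dt_s")
    if e.n_fields < 1 or e.n_flights_per_field < 1:
        raise ConfigError("experiment.n_fields and n_flights_per_field must be >= 1")
    if len(e.start_x_range_m) != 2 or not 0 < e.start_x_range_m[0] <= e.start_x_range_m[1]:
        raise ConfigError("experiment.start_x_range_m must be (lo, hi) with 0 < lo <= hi")
    if e.start_y_halfwidth_m < 0:
        raise ConfigError("experiment.start_y_halfwidth_m must be >= 0")
    if not e.max_sim_time_s > 0:
        raise ConfigError("experiment.max_sim_time_s must be > 0")
    if e.spin_up_s is not None and e.spin_up_s < 0:
        raise ConfigError("experiment.spin_up_s must be >= 0")
    if any(ti < 0 for ti in e.ti_grid) or len(e.ti_grid) == 0:
        raise ConfigError("experiment.ti_grid must be non-empty with values >= 0")
    if any(r <= 0 for r in e.radii_m) or len(e.radii_m) == 0:
        raise ConfigError("experiment.radii_m must be non-empty with values > 0")
    if e.metrics_radius_m <= 0:
        raise ConfigError("experiment.metrics_radius_m must be > 0")


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON config file; an empty file yields full defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def write_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved config as YAML (or JSON by suffix)."""
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Per-condition model resolution
# ---------------------------------------------------------------------------

def spin_up_time(cfg: SimulationConfig) -> float:
    """Field spin-up before fliers are placed: 1.5 x (max start distance) / U."""
    if cfg.experiment.spin_up_s is not None:
        return float(cfg.experiment.spin_up_s)
    return 1.5 * cfg.experiment.start_x_range_m[1] / cfg.wind.u_mean


def resolve_condition(
    cfg: SimulationConfig, ti: float | None = None
) -> tuple[WindModel, PlumeModel, NavigatorParams]:
    """Concrete models for one turbulence-intensity condition.

    Fills the derived plume parameters: growth rates A = growth_coupling *
    TI * U unless overridden, and the detection threshold from the
    calibration reference unless set explicitly.
    """
    if ti is None:
        ti = cfg.wind.turbulence_intensity
    w, p, n = cfg.wind, cfg.plume, cfg.navigator
    wind = WindModel(
        u_mean=w.u_mean,
        turbulence_intensity=ti,
        gust_enabled=w.gust.enabled,
        gust_amplitude_frac=w.gust.amplitude_frac,
        gust_hold_s=w.gust.hold_s,
        gust_rate_per_run=w.gust.rate_per_run,
        meander_enabled=w.meander.enabled,
        meander_amplitude=w.meander.amplitude,
        meander_period_s=w.meander.period_s,
    )
    a_h = p.a_h if p.a_h is not None else growth_rate_from_ti(ti, w.u_mean, p.growth_coupling)
    a_z = p.a_z if p.a_z is not None else growth_rate_from_ti(ti, w.u_mean, p.growth_coupling)
    plume = PlumeModel(
        pulse_interval_s=p.pulse_interval_s,
        mass_per_pulse=p.mass_per_pulse,
        a_h=a_h,
        a_z=a_z,
        b_h=p.b_h,
        b_z=p.b_z,
        z0_m=p.z0_m,
        threshold=1.0,  # placeholder, replaced below
        sigma_floor_m=p.sigma_floor_m,
        vertical_term=p.vertical_term,
    )
    if p.threshold is not None:
        threshold = p.threshold
    else:
        # one fixed sensor threshold for the whole sweep, anchored at the
        # calibration's reference turbulence intensity
        cal = p.calibration
        a_ref_h = p.a_h if p.a_h is not None else growth_rate_from_ti(cal.ti_ref, w.u_mean, p.growth_coupling)
        a_ref_z = p.a_z if p.a_z is not None else growth_rate_from_ti(cal.ti_ref, w.u_mean, p.growth_coupling)
        plume_ref = replace(plume, a_h=a_ref_h, a_z=a_ref_z)
        threshold = calibrate_threshold(plume_ref, w.u_mean, cal.x_ref_m, cal.rho_ref_m)
    plume = replace(plume, threshold=threshold)
    nav = NavigatorParams(
        ground_speed=n.ground_speed,
        alpha_min_deg=n.alpha_min_deg,
        alpha_max_deg=n.alpha_max_deg,
        strategy=n.strategy,
        internal_counter_tau_s=n.internal_counter_tau_s,
        surge_timer_origin=n.surge_timer_origin,
    )
    return wind, plume, nav


# ---------------------------------------------------------------------------
# Seed tree
# ---------------------------------------------------------------------------

def _ti_key(ti: float) -> int:
    return int(round(ti * 1_000_000))


def child_seedseq(master: int, *key: int) -> np.random.SeedSequence:
    """Named child stream of the master seed (counter-based spawn key)."""
    return np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))


def field_seedseq(master: int, ti: float, field_i: int) -> np.random.SeedSequence:
    return child_seedseq(master, 1, _ti_key(ti), field_i)


def flight_seedseq(master: int, ti: float, field_i: int, flight_j: int) -> np.random.SeedSequence:
    return child_seedseq(master, 2, _ti_key(ti), field_i, flight_j)


def kernel_seed(ss: np.random.SeedSequence) -> int:
    """31-bit integer seed for the compiled flight kernel."""
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Run manifest and tabular output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Provenance block embedded in every output file.

    The hash covers the resolved config and master seed (not the timestamp),
    so re-running from the same manifest reproduces outputs bit-identically
    and mismatched replays are detectable.
    """

    config: dict
    seed: int
    version: str
    timestamp: str
    hash: str


def make_manifest(cfg: SimulationConfig) -> RunManifest:
    config = config_to_dict(cfg)
    payload = json.dumps({"config": config, "seed": cfg.seed, "version": VERSION}, sort_keys=True)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    return RunManifest(
        config=config,
        seed=cfg.seed,
        version=VERSION,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        hash=digest,
    )


def write_table(df, path: str | Path, manifest: RunManifest | None = None) -> None:
    """RFC-4180 CSV with a commented manifest header block.

    Read back with ``pandas.read_csv(path, comment='#')``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if manifest is not None:
            fh.write(f"# mothnav {manifest.version} manifest_hash={manifest.hash} seed={manifest.seed}\n")
            fh.write("# config: " + json.dumps(manifest.config, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Test / demonstration fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "paper_defaults",
    "zero_turbulence_straight_shot",
    "single_puff_chord",
    "tuned_internal_counter",
)


def make_fixture(name: str) -> SimulationConfig:
    """Small documented scenario configs used by the test suite.

    ``paper_defaults``
        the full default condition set (TI grid 5-30%, radii 0.15/0.20/0.25 m,
        10 fields x 100 flights).
    ``zero_turbulence_straight_shot``
        zero turbulence, explicit plume constants: puffs advect exactly along
        the centerline and a flier started inside the puff train flies a
        deterministic, successful path to the source.
    ``single_puff_chord``
        a single frozen-size puff (growth exponent 0) sweeping over a
        stationary flier: the crossing-time oracle t_c = 2 rho / U.
    ``tuned_internal_counter``
        the fixed-counter baseline with tau set to a typical measured
        crossing time of the default calibrated geometry.
    """
    if name == "paper_defaults":
        return SimulationConfig()
    if name == "zero_turbulence_straight_shot":
        # threshold low enough that the detectable radius (~0.6 m) exceeds the
        # puff spacing: the corridor is connected, detection never drops, and
        # the flight is a pure upwind surge at constant y
        return SimulationConfig(
            wind=WindConfig(u_mean=1.0, turbulence_intensity=0.0),
            plume=PlumeConfig(a_h=0.02, a_z=0.02, threshold=3.0e-4),
            experiment=ExperimentConfig(
                n_fields=1,
                n_flights_per_field=1,
                ti_grid=(0.0,),
                start_x_range_m=(5.0, 5.0),
                start_y_halfwidth_m=0.05,
                max_sim_time_s=120.0,
                spin_up_s=0.0,
            ),
        )
    if name == "single_puff_chord":
        return SimulationConfig(
            wind=WindConfig(u_mean=1.0, turbulence_intensity=0.0),
            plume=PlumeConfig(
                pulse_interval_s=1000.0,
                a_h=0.2,
                a_z=0.2,
                b_h=0.0,
                b_z=0.0,
                # peak * exp(-1/2): the detectable radius equals sigma_h = 0.2 m
                threshold=4.8153,
            ),
            experiment=ExperimentConfig(
                n_fields=1,
                n_flights_per_field=1,
                ti_grid=(0.0,),
                start_x_range_m=(5.0, 5.0),
                start_y_halfwidth_m=0.0,
                max_sim_time_s=30.0,
                spin_up_s=0.0,
            ),
        )
    if name == "tuned_internal_counter":
        return SimulationConfig(
            navigator=NavigatorConfig(strategy="internal_counter", internal_counter_tau_s=0.3),
            experiment=ExperimentConfig(
                n_fields=2,
                n_flights_per_field=25,
                ti_grid=(0.15,),
            ),
        )
    raise ConfigError(f"unknown fixture name {name!r}; known: {FIXTURE_NAMES}")
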