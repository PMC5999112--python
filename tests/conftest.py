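import dataclasses

import numpy as np
import pytest

import mothnav as mn


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_cfg():
    return mn.SimulationConfig()


@pytest.fixture
def small_cfg():
    """Reduced-replication config for fast Monte-Carlo checks."""
    cfg = mn.SimulationConfig()
    return dataclasses.replace(
        cfg,
        experiment=dataclasses.replace(
            cfg.experiment, n_fields=2, n_flights_per_field=15, ti_grid=(0.15,)
        ),
    )


def build_fixture_field(name: str, ti: float = 0.0):
    """Build the plume field of a named scenario config."""
    cfg = mn.make_fixture(name)
    wind, plume, nav = mn.resolve_condition(cfg, ti)
    from mothnav.config import spin_up_time

    exp = cfg.experiment
    spin = spin_up_time(cfg)
    frng = np.random.default_rng(1)
    field = mn.build_field(
        wind,
        plume,
        spin + exp.max_sim_time_s,
        exp.dt_s,
        exp.start_x_range_m[1] + exp.prune_margin_m,
        frng,
    )
    return cfg, field, nav, spin
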