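"""Shared fixtures: resolved parameter sets and steady-state runs.

The steady-state simulations are deterministic and moderately costly,
so the runs for the three shipped configurations are session-scoped and
shared between the metric, integrator and acceptance tests.
"""

import pytest

import avianlung as al


@pytest.fixture(scope="session")
def default_params() -> al.ModelParameters:
    return al.load_parameters(preset="default")


@pytest.fixture(scope="session")
def default_run(default_params):
    """Steady-state run with the duck default parameters."""
    return al.simulate_to_steady_state(default_params)


@pytest.fixture(scope="session")
def fig7a_run():
    """Inspiratory-valving-only configuration (expiratory condition at equality)."""
    p = al.load_parameters(preset="fig7a")
    return p, al.simulate_to_steady_state(p)


@pytest.fixture(scope="session")
def fig7b_run():
    """Expiratory-valving-only configuration (inspiratory condition at equality)."""
    p = al.load_parameters(preset="fig7b")
    return p, al.simulate_to_steady_state(p)


@pytest.fixture(scope="session")
def borderline_params() -> al.ModelParameters:
    """No valving at all: gamma = 1 and equal resistances in both branches."""
    cfg = al.preset_config("default")
    cfg.update(gamma=1.0, R1_insp=3.0, R2_exp=3.0, R2_insp=3.0, R1_exp=3.0)
    cfg.pop("k_insp")
    cfg.pop("k_exp")
    return al.resolve_parameters(cfg)
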