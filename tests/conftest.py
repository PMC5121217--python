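import dataclasses

import pytest

from mccflux.species import default_registry
from mccflux.simulate import default_reactor_config, generate_reactor_timeseries


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def noiseless_run():
    """One noiseless Phase-II-like simulation shared across tests."""
    cfg = default_reactor_config(seed=1, noise_cv=0.0)
    frame, truth = generate_reactor_timeseries(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def noisy_run():
    cfg = default_reactor_config(seed=1, noise_cv=0.05)
    frame, truth = generate_reactor_timeseries(cfg)
    return cfg, frame, truth


@pytest.fixture()
def fast_config():
    """Small two-period config for quick structural tests."""
    cfg = default_reactor_config(seed=3, noise_cv=0.0)
    return dataclasses.replace(
        cfg,
        periods=cfg.periods[:2],
        production={pid: cfg.production[pid] for pid in ("P2", "P3")},
    )
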