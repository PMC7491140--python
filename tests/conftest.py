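import numpy as np
import pytest

from yllburden.simulate import SimConfig, TrueSurface, gen_outcomes, gen_weather


@pytest.fixture(scope="session")
def small_cfg():
    """Two-year single-location configuration for fast fits."""
    return SimConfig(n_locations=2, n_days=2 * 365, seed=901)


@pytest.fixture(scope="session")
def surface():
    return TrueSurface()


@pytest.fixture(scope="session")
def fitted_location(surface):
    """One fitted 5-year location, shared across tests that only read it."""
    from yllburden.dlnm import DLNMModel

    cfg = SimConfig(n_locations=1, n_days=5 * 365, seed=314)
    weather = gen_weather(cfg, 0)
    daily, _ = gen_outcomes(cfg, weather, surface, 0, with_records=False)
    model = DLNMModel(
        daily["yll_rate"].to_numpy(),
        daily["tmean"].to_numpy(),
        daily["rh"].to_numpy(),
        daily["dow"].to_numpy(),
    )
    results = model.fit()
    reduced = results.reduce(center=float(np.median(daily["tmean"])))
    return cfg, daily, results, reduced
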