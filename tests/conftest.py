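import numpy as np
import pandas as pd
import pytest

from cinevoc import simulate
from cinevoc.linkage import EvaluationPlan


@pytest.fixture(scope="session")
def tiny_scenario():
    return simulate.RoomScenario(
        volume=800.0, air_exchanges_per_hour=6.0,
        background={"co2": 400.0, "m69.070": 0.2}, time_step=30.0)


@pytest.fixture(scope="session")
def quiet_instrument():
    """Instrument at constant reference conditions, all noise off, and a
    primary-ion denominator that is exactly 1e6 so that the raw counts
    equal the normalized counts bit for bit."""
    return simulate.InstrumentModel(
        sensitivity={m: 1.0 for m in simulate.DEFAULT_MASSES},
        m21_baseline=1600.0, m39_baseline=800.0,   # 500*1600+250*800 = 1e6
        primary_drift=0.0, temperature_jitter=0.0, pressure_jitter=0.0,
        drift_temperature=298.15, drift_pressure=2.0,
        counting_noise=False)


@pytest.fixture(scope="session")
def fast_plan():
    return EvaluationPlan(n_repeats=5, n_trees=30, seed=7)


def make_grid_frame(values: dict, step: float = 30.0) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    idx = pd.Index(np.arange(n) * step, name="time_s")
    return pd.DataFrame(values, index=idx)


@pytest.fixture
def grid_frame():
    return make_grid_frame
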