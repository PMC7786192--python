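import numpy as np
import pandas as pd
import pytest

from reactnorm import scenario


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small combined-scenario dataset shared by likelihood-level tests."""
    return scenario("combined", n=20, m=50, seed=7)


@pytest.fixture(scope="session")
def mid_dataset():
    """Medium dataset for fit-level checks."""
    return scenario("combined", n=150, m=300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def weather_constant():
    """Two stations, 120 days of constant weather."""
    days = pd.date_range("2015-01-01", periods=120, freq="D")
    frames = []
    for sid, (t, h) in {"S1": (20.0, 60.0), "S2": (30.0, 50.0)}.items():
        frames.append(pd.DataFrame({
            "station_id": sid, "date": days, "t_max": t, "rh_mean": h,
        }))
    return pd.concat(frames, ignore_index=True)
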