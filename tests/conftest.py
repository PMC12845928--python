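import numpy as np
import pytest

from actigate import SensorSession


def make_session(values, rate=50.0, signal="Force", role="baseline", times=None, **kw):
    """Build a small session around a value array (1-D for Force, (n,3) for Acc)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if times is None:
        times = np.arange(n) / rate
    defaults = dict(
        sensor_kind="cosmo_switch" if signal == "Force" else "movesense_motion",
        signal=signal,
        units="N" if signal == "Force" else "g",
        sample_rate_hz=rate,
        placement="left wrist",
        role=role,
    )
    defaults.update(kw)
    return SensorSession(times=times, values=values, **defaults)


def random_session(rng, n=None, signal="Acc"):
    """A random but valid session for round-trip style tests."""
    n = n or int(rng.integers(1, 400))
    k = 3 if signal in ("Acc", "Gyr", "Mag") else 1
    times = np.cumsum(rng.uniform(0.005, 0.04, size=n))
    values = rng.normal(scale=rng.uniform(0.1, 10.0), size=(n, k))
    rate = 1.0 / float(np.median(np.diff(times))) if n > 1 else 50.0
    return make_session(values, rate=rate, signal=signal, times=times)


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
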