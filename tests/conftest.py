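import numpy as np
import pytest

from circasync import LightRegime, SimParams, TimeSeriesSet, simulate_panel


@pytest.fixture
def hourly_week():
    """Hourly grid over 7 days, the standard experiment length."""
    return np.arange(0.0, 168.0)


@pytest.fixture
def pure_cosine(hourly_week):
    """Noiseless 25.5-h cosine, amplitude 10, peak at 6 h, offset 100."""
    return 100 + 10 * np.cos(2 * np.pi * (hourly_week - 6) / 25.5)


@pytest.fixture
def small_frl_panel():
    """A small free-running panel: heterogeneous periods, damping, noise."""
    params = SimParams(n_reps=6, duration_hours=168, seed=11)
    return simulate_panel(params, LightRegime("FRL", 24, 24))


@pytest.fixture
def identical_panel():
    """Three bit-identical noiseless cosine replicates on a full 168-h grid."""
    times = np.arange(0.0, 169.0)  # 0..168 inclusive
    y = np.cos(2 * np.pi * (times - 6) / 24)
    return TimeSeriesSet(
        times=times,
        signals=np.tile(y, (3, 1)),
        regime=LightRegime("FRL", 24, 24),
    )
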