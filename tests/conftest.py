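import numpy as np
import pytest

from tempatterns.events import EventStream


@pytest.fixture
def delay5_stream() -> EventStream:
    """20 well-separated A-events, each followed by a B at exactly 5 s."""
    ta = np.arange(20) * 50.0
    events = [(t, "A") for t in ta] + [(t + 5.0, "B") for t in ta]
    return EventStream(events, span=1000.0)


def poisson_pair_stream(seed: int, rate: float = 0.1, span: float = 1e4) -> EventStream:
    """Two independent homogeneous Poisson processes on a common span."""
    rng = np.random.default_rng(seed)
    n_draw = int(rate * span * 1.3) + 50
    ta = np.cumsum(rng.exponential(1.0 / rate, n_draw))
    tb = np.cumsum(rng.exponential(1.0 / rate, n_draw))
    events = [(float(t), "A") for t in ta if t < span]
    events += [(float(t), "B") for t in tb if t < span]
    return EventStream(events, span=span)


def lagged_pair_stream(
    seed: int, lag: float = 1.0, jitter: float = 0.05, rate: float = 0.1, span: float = 1e4
) -> EventStream:
    """Every B trails an A by ``lag`` +- ``jitter`` seconds."""
    rng = np.random.default_rng(seed)
    ta = np.cumsum(rng.exponential(1.0 / rate, int(rate * span * 1.3) + 50))
    ta = ta[ta < span - lag - 5 * jitter]
    tb = ta + rng.normal(lag, jitter, len(ta))
    events = [(float(t), "A") for t in ta] + [(float(t), "B") for t in tb if 0 < t < span]
    return EventStream(events, span=span)
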