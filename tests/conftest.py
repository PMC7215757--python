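import numpy as np
import pytest

from releasekit import DEFAULT_TIMES_H, FirstOrderParams, ReleaseCurve, eval_first_order


@pytest.fixture
def times():
    return np.asarray(DEFAULT_TIMES_H)


@pytest.fixture
def slow_params():
    """Slow-releasing formulation: low asymptote, small rate constant."""
    return FirstOrderParams(a=80.0, b=0.03)


@pytest.fixture
def fast_params():
    """Fast-releasing formulation: asymptote slightly above 100%."""
    return FirstOrderParams(a=105.0, b=0.3)


@pytest.fixture
def noiseless_curve(times, slow_params):
    return ReleaseCurve(times, eval_first_order(slow_params, times), label="slow")
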