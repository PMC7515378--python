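import numpy as np
import pytest

#: 12-sample worked example used throughout: its d=3 symbolization,
#: weights and network edges are known by hand.
TOY_SERIES = [1, 3, 4, 5, 4, 5, 3, 1, 2, 4, 5, 3]

TOY_CODES = [123, 123, 132, 213, 312, 321, 231, 123, 123, 312]

TOY_WEIGHTS = [1.5556, 0.6667, 0.2222, -0.2222, 0.6667, 2.6667, -0.6667, -1.5556, 1.5556, 0.6667]


@pytest.fixture
def toy_series():
    return np.asarray(TOY_SERIES, dtype=float)


@pytest.fixture
def period5_long():
    """Period-5 ramp 1..5 repeated to length 20,480."""
    from npentropy import periodic_signal

    return periodic_signal([1, 2, 3, 4, 5], 20480)
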