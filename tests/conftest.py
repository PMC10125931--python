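import numpy as np
import pandas as pd
import pytest

from speedacc import DesignSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_trials():
    """Hand-checkable trial table: 2 participants x 2 conditions."""
    rows = [
        # participant, condition, rt, correct
        (1, 1, 400.0, 1),
        (1, 1, 500.0, 1),
        (1, 1, 600.0, 0),
        (1, 2, 450.0, 1),
        (1, 2, 550.0, 1),
        (1, 2, 650.0, 1),
        (2, 1, 300.0, 1),
        (2, 1, 700.0, 0),
        (2, 1, 500.0, 1),
        (2, 2, 400.0, 1),
        (2, 2, 600.0, 1),
        (2, 2, 500.0, 0),
    ]
    return pd.DataFrame(rows, columns=["participant", "condition", "rt", "correct"])


def small_sat_spec(**overrides):
    """Threshold-manipulation design at desk scale (fast unit tests)."""
    kw = dict(
        focal="threshold",
        mu=(120.0, 130.0),
        fixed=0.25,
        sigma_b2=400.0,
        sigma_w2=100.0,
        n_participants=6,
        n_trials=50,
        seed=5,
    )
    kw.update(overrides)
    return DesignSpec(**kw)


@pytest.fixture
def sat_spec_small():
    return small_sat_spec()
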