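import numpy as np
import pandas as pd
import pytest

from driftfit import CellDesign, DiffusionParams, simulate_condition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trials(rts, responses, stimulus_classes, condition="test",
                participant="p1", group="g"):
    """Small hand-built trial table."""
    n = len(rts)
    return pd.DataFrame({
        "participant": participant, "group": group, "condition": condition,
        "stimulus_class": list(stimulus_classes) if not isinstance(
            stimulus_classes, str) else [stimulus_classes] * n,
        "response": list(responses) if not isinstance(responses, str)
        else [responses] * n,
        "rt": list(rts),
        "censored": False,
    })


@pytest.fixture
def make_trials_fn():
    return make_trials


OLD_BIAS_CELL = CellDesign(
    condition="test", class_counts={"old": 140, "new": 70},
    class_drifts={"old": 0.04, "new": -0.14},
    base=DiffusionParams(v=0.0, a=0.14, zr=0.66, t0=0.6, s=0.1))


@pytest.fixture(scope="session")
def exp1_participant():
    """One simulated ratio-manipulation participant (210 trials)."""
    rng = np.random.default_rng(777)
    return simulate_condition(OLD_BIAS_CELL, 4.0, rng, "p1", "old-bias")
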