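import numpy as np
import pandas as pd
import pytest

from emobias.simulate import DesignSpec, ObserverParams, simulate_observer


def make_trials(pid: str, spec: list[tuple[int, str, int]]) -> pd.DataFrame:
    """Build a toy trial frame from (morph_level, response, count) triples."""
    rows = []
    index = 1
    for level, response, count in spec:
        for _ in range(count):
            rows.append({"participant_id": pid, "trial_index": index,
                         "morph_level": level, "face_id": "", "response": response})
            index += 1
    return pd.DataFrame(rows)


@pytest.fixture
def step_observer_trials() -> pd.DataFrame:
    """Deterministic attentive observer: sigma -> 0, mu = 0, no omissions."""
    params = ObserverParams(mu=0.0, sigma=0.01)
    return simulate_observer(params, seed=0, participant_id="step")


@pytest.fixture
def synthetic_observer_trials() -> pd.DataFrame:
    """One realistic 64-trial observer with omissions."""
    params = ObserverParams(mu=5.0, sigma=12.0, omission_rate=0.08)
    return simulate_observer(params, seed=42, participant_id="sim")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
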