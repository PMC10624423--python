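import numpy as np
import pandas as pd
import pytest

from trialhist import SynthConfig, behavior


def table_from_outcomes(outcomes, session_ids=None):
    """Build a trial table from a list of outcome labels (one session unless given)."""
    inv = {"Hit": ("go", 1), "Miss": ("go", 0), "FA": ("nogo", 1), "CR": ("nogo", 0)}
    rows = []
    for i, o in enumerate(outcomes):
        tex, lick = inv[o]
        rows.append(
            {
                "trial_index": i + 1,
                "session_id": "s1" if session_ids is None else session_ids[i],
                "texture": tex,
                "licked": lick,
                "outcome": o,
                "t_texture_stop_s": 8.0 + 12.0 * i,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_table(rng):
    """A 1000-trial table with random textures and licks."""
    tex = np.where(rng.random(1000) < 0.5, "go", "nogo")
    lick = rng.random(1000) < 0.5
    out = [behavior.classify_outcome(t, bool(l)) for t, l in zip(tex, lick)]
    sess = np.where(np.arange(1000) < 500, "day01", "day02")
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, 1001),
            "session_id": sess,
            "texture": tex,
            "licked": lick.astype(int),
            "outcome": out,
            "t_texture_stop_s": 8.0 + 12.0 * np.arange(1000),
        }
    )


@pytest.fixture
def small_config():
    """A quick-to-simulate subject with a mid-course history onset."""
    return SynthConfig(
        n_trials=900,
        n_sessions=3,
        learn_b=300,
        learn_c=80,
        history_onset_learning=450,
        history_effect=0.03,
        noise_sd=0.04,
        contamination_amp=0.0,
        seed=7,
    )
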