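import numpy as np
import pandas as pd
import pytest

from ensemble_ddm.simulate import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """A small full-design cohort (6 subjects x 9 cells x 25 trials)."""
    rng = np.random.default_rng(4242)
    df, subjects = generate_cohort(6, 25, rng, dt=1e-3)
    return df, subjects


def make_single_subject_df(rng, n=40, attn="general"):
    """Minimal valid trial table for one subject."""
    return pd.DataFrame(
        {
            "subject_id": 1,
            "attn": attn,
            "stim": rng.choice(["neutral", "fearful", "happy"], size=n),
            "choice": rng.choice(["upper", "lower"], size=n),
            "rt_s": rng.uniform(0.3, 1.5, size=n),
        }
    )
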