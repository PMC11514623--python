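import numpy as np
import pandas as pd
import pytest

import latentiv as lv
from latentiv.synthetic_data import MODEL_TEXT


@pytest.fixture(scope="session")
def brain_body_text() -> str:
    return MODEL_TEXT


@pytest.fixture(scope="session")
def brain_body_spec(brain_body_text):
    return lv.parse_model(brain_body_text)


@pytest.fixture(scope="session")
def brain_body_system(brain_body_spec):
    return lv.transform(brain_body_spec)


@pytest.fixture(scope="session")
def default_gen():
    return lv.default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort70():
    """One default synthetic cohort (n = 70, 3 MCAR organ cells)."""
    return lv.generate(lv.default_params(), seed=42)


@pytest.fixture(scope="session")
def complete_cohort():
    """A complete (no-missing) cohort of 300 rows for estimator tests."""
    p = lv.default_params().with_(n=300, missing_var=None)
    return lv.generate(p, seed=7)


def make_eight_row_table() -> pd.DataFrame:
    """Fixed 8-row table for the stage-wise 2SLS oracle."""
    return pd.DataFrame(
        {
            "y": [2.1, 3.9, 6.2, 7.8, 10.3, 12.1, 13.8, 16.2],
            "x": [1.0, 2.1, 2.9, 4.2, 5.1, 5.8, 7.2, 7.9],
            "z1": [0.9, 2.0, 3.1, 3.8, 5.2, 6.1, 6.8, 8.1],
            "z2": [1.2, 1.8, 3.3, 4.1, 4.8, 6.3, 7.1, 7.7],
        }
    )
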