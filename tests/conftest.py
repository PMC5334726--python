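import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# subset-fit exclusions and dropped-row notices are expected noise in tests
logging.getLogger("naturedose").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_survey() -> pd.DataFrame:
    """A 600-respondent synthetic survey shared across tests."""
    from naturedose import synthetic as syn

    return syn.generate_survey(syn.default_config(n_respondents=600, seed=7)).data


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_risk_data(rng: np.random.Generator, n: int, k: int,
                     beta0: float = -1.0, scale: float = 0.8) -> tuple:
    """A random binary-risk-factor dataset and its factor column names."""
    cols = tuple(f"f{i}" for i in range(k))
    df = pd.DataFrame({c: rng.integers(0, 2, n).astype(float) for c in cols})
    betas = rng.normal(0.0, scale, size=k)
    eta = beta0 + df[list(cols)].to_numpy() @ betas
    df["depression"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return df, cols
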