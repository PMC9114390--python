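import numpy as np
import pandas as pd
import pytest

from guiltgame.task_design import generate_design
from guiltgame.synthetic_population import (
    CountryConfig,
    PopulationConfig,
    generate_study,
)


@pytest.fixture(scope="session")
def design45():
    """Default 45-trial design under the stock correlation bounds."""
    return generate_design(seed=1)


@pytest.fixture(scope="session")
def design_frame(design45):
    return design45.to_frame()


@pytest.fixture(scope="session")
def small_cfg():
    """A cut-down two-cohort configuration for fast end-to-end tests."""
    return PopulationConfig(
        countries=[
            CountryConfig("KR-like", 40, 0.6, "neuroticism", 0.15),
            CountryConfig("UK-like", 40, 0.55, "conscientiousness", 0.15),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg, design45):
    return generate_study(small_cfg, seed=3, design=design45)


def simulate_subject(design, gamma, alpha, seed, temperature=1.0, intercept=0.0, pid="s0"):
    """One subject's combined-model choice record on a design."""
    frame = design.to_frame()
    eta = temperature * (
        frame["reward"].to_numpy()
        + gamma * frame["guilt"].to_numpy()
        + alpha * frame["inequity_abs"].to_numpy()
    ) + intercept
    rng = np.random.default_rng(seed)
    y = (rng.random(len(frame)) < 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))).astype(int)
    return pd.DataFrame(
        {"pid": pid, "trial_id": frame["trial_id"].to_numpy(), "choice": y}
    )
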