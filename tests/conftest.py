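import numpy as np
import pandas as pd
import pytest

from epiclock.preprocess import BetaMatrix
from epiclock.synth import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=60,
        n_cpgs=600,
        n_lmrs=12,
        lmr_cpg_range=(5, 10),
        n_signal_features=20,
        effect_size=0.012,
        n_age_features=20,
        seed=42,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_beta():
    """3 CpGs x 4 samples, handy for arithmetic checks."""
    values = pd.DataFrame(
        [[0.2, 0.3, 0.25, 0.4], [0.4, 0.5, 0.45, 0.6], [0.8, 0.7, 0.75, 0.9]],
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return BetaMatrix(values=values, feature_level="cpg")
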