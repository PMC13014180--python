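import numpy as np
import pandas as pd
import pytest

from sulcnet._atlas import CANONICAL_SULCI, CORE_PHENOTYPES
from sulcnet.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject default cohort shared across read-only tests."""
    return simulate_cohort(CohortSpec(n_cases=30, n_controls=30, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """100/100 default cohort (seed 7) for eigen-fold recovery tests."""
    return simulate_cohort(CohortSpec(n_cases=100, n_controls=100, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_subject_frame(rng, n_sulci=40):
    """One subject's sulci x phenotype frame with distinct random values."""
    return pd.DataFrame(
        rng.normal(size=(n_sulci, len(CORE_PHENOTYPES))),
        index=list(CANONICAL_SULCI[:n_sulci]),
        columns=list(CORE_PHENOTYPES),
    )
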