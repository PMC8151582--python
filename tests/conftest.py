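import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ehgkit.pipeline import (
    null_study_config,
    run_null_study,
    run_pipeline,
    scaled_study_config,
)
from ehgkit.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """Three labelled subjects at the minimum duration (two+ windows)."""
    cfg = SyntheticCohortConfig(n_term=2, n_preterm=1, duration_s=240, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def scaled_result():
    """Full pipeline on the desk-scale study conditions (60 term / 12
    preterm, 10 partitions, capped GA).  Shared across tests: several
    end-to-end properties are asserted against this single run."""
    return run_pipeline(scaled_study_config(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Feature table, screening and metrics for a cohort with zero planted
    class effect (both classes share all generator parameters)."""
    return run_null_study(null_study_config(seed=5))
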