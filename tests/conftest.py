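import numpy as np
import pytest

import pepage as pp


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (3 ages x 13, 200 peptides, 10 planted)."""
    config = pp.SimulationConfig(seed=7)
    profiles, design, truth = pp.generate_cohort(config)
    return config, profiles, design, truth


@pytest.fixture(scope="session")
def matched_default_cohort(default_cohort):
    """The default cohort normalized and matched into a master matrix."""
    config, profiles, design, truth = default_cohort
    reference = pp.reference_standards(config)
    normalized = pp.normalize_cohort(profiles, reference)
    matrix = pp.match_profiles(normalized, reference=reference)
    return config, matrix, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
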