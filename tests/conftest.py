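import warnings

import numpy as np
import pytest

from amypanel.cohort import apply_transforms
from amypanel.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort (n=200, 40-analyte panel, 6 planted signals)."""
    cfg = SyntheticConfig(
        n_subjects=200, n_analytes=40, n_signal=6, blocks=((2, 0.7),), seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def transformed_small(small_cohort):
    table, truth = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return apply_transforms(table), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
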