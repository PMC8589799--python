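import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from longiperf.radiomics import extract_cohort_features
from longiperf.synthetic_cohort import (
    CohortConfig,
    fixture_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Miniature 16-cubed in-memory cohort (2 subjects per class, 2 tps)."""
    return generate_cohort(fixture_config(seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return extract_cohort_features(tiny_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-grid cohort sized like a multi-time-point surveillance arm
    (8 PD / 5 PsP / 6 SD)."""
    cfg = CohortConfig(n_per_class=(8, 5, 6), seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


def split_xy(feature_table: pd.DataFrame):
    y = feature_table["class_label"]
    X = feature_table.drop(
        columns=[c for c in ("class_label", "rater_label") if c in feature_table]
    )
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
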