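"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from assocmod import (
    default_spec,
    null_spec,
    simulate_training_cohort,
    simulate_validation_cohorts,
)
from assocmod.pipeline import preprocess_training
from assocmod.validation import prepare_validation_cohort


@pytest.fixture(scope="session")
def training_default():
    """Default training cohort (2000 genes, 60 samples, one planted cis module)."""
    bundle, truth = simulate_training_cohort(default_spec(seed=1))
    return bundle, truth


@pytest.fixture(scope="session")
def training_processed(training_default):
    bundle, truth = training_default
    expr_cdf, arm_cnv, meth = preprocess_training(bundle)
    return expr_cdf, arm_cnv, meth, bundle.annotation, truth


@pytest.fixture(scope="session")
def validation_default():
    """Default validation cohorts: survival effect only in EastAsian-female."""
    cohorts, truth = simulate_validation_cohorts(default_spec(seed=1))
    return cohorts, truth


@pytest.fixture(scope="session")
def null_cohort_prepared():
    """One fully null validation cohort, CDF-normalized, with clinical table."""
    cohorts, _ = simulate_validation_cohorts(null_spec(seed=11, n_samples=150))
    return prepare_validation_cohort(cohorts[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chromosome": ["7", "7", "7", "3"],
            "arm": ["p", "p", "q", "p"],
            "position": [1000, 2000, 3000, 4000],
        }
    )
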