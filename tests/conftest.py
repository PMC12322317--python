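"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from npscreen import (
    CohortConfig,
    apply_inclusion_filters,
    generate_cohort,
    generate_null_cohort,
    load_labels,
)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_unlabeled=400, n_labeled=300, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_null_cohort(small_config):
    return generate_null_cohort(small_config)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    labels, cutoffs = load_labels(small_cohort.neuropathology)
    return labels


@pytest.fixture(scope="session")
def small_sets(small_cohort):
    gen = apply_inclusion_filters(small_cohort, "generalized", seed=1)
    t_minus = apply_inclusion_filters(small_cohort, "t_minus", seed=1)
    return gen, t_minus


def single_visit(visits: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One random visit per participant, indexed by participant."""
    return (
        visits.groupby("participant_id")
        .sample(1, random_state=seed)
        .set_index("participant_id")
    )
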