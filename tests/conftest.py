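"""Shared fixtures: one synthetic stress study reused across test modules."""

import numpy as np
import pytest

from hrvstress import (
    clean_rr,
    default_sim_config,
    extract_all,
    generate,
    segment_epochs,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (series, segments, truth), fixed seed."""
    return generate(default_sim_config(seed=7))


@pytest.fixture(scope="session")
def epoch_set(study):
    series, segments, _ = study
    return segment_epochs(clean_rr(series), segments)


@pytest.fixture(scope="session")
def feature_table(epoch_set):
    """22-feature table of the default study at all five scales."""
    return extract_all(epoch_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
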