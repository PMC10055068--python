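"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from cortexg.synthetic import SyntheticConfig, generate_expression_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """A default-noise atlas small enough for fast unit tests."""
    cfg = SyntheticConfig(seed=11, n_genes=600, n_inconsistent_genes=30,
                          n_specific_genes=5)
    profiles, summary, truth = generate_expression_atlas(cfg)
    return cfg, profiles, summary, truth


@pytest.fixture(scope="session")
def noiseless_atlas():
    """Exact rank-2 atlas: no noise, no offset, perfect simple structure."""
    cfg = SyntheticConfig(seed=7, n_genes=300, noise_sd=0.0, donor_noise_sd=0.0,
                          hemisphere_offset=0.0, cross_loading=0.0,
                          n_inconsistent_genes=0, n_specific_genes=0)
    profiles, summary, truth = generate_expression_atlas(cfg)
    return cfg, profiles, summary, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def regional_series(values, name="map"):
    """Helper: wrap values into a hemisphere-labelled regional Series."""
    from cortexg.atlas import region_labels

    n = len(values)
    assert n % 2 == 0
    labels = region_labels(n // 2)
    return pd.Series(np.asarray(values, dtype=float), index=labels, name=name)
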