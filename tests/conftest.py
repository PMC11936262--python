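"""Shared fixtures: synthetic corpora at the default study conditions.

Session-scoped so the descriptive-statistics tests and the acceptance tests
reuse the same generated data.
"""

import numpy as np
import pytest

from misscan import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    """Default study conditions: 100 proteins, 300-800 residues, X-ray-like
    class mix and score distributions."""
    return GeneratorConfig(n_proteins=100, seed=20240301)


@pytest.fixture(scope="session")
def default_corpus(default_config):
    return generate_corpus(default_config)


@pytest.fixture(scope="session")
def learner_corpus():
    """Larger corpus for the recurrent-labeler checks (200 proteins)."""
    return generate_corpus(GeneratorConfig(n_proteins=200, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
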