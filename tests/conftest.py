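import numpy as np
import pandas as pd
import pytest

from caoss.embeddings import EmbeddingTable
from caoss.lexicon import CompoundEntry, CompoundLexicon
from caoss.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Scaled-down generator settings for fast unit tests."""
    return SyntheticConfig(d=16, n_characters=60, n_compounds=400, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def toy_table() -> EmbeddingTable:
    return EmbeddingTable(
        dimension=3,
        entries={
            "a": np.array([1.0, 0.0, 0.0]),
            "b": np.array([0.0, 1.0, 0.0]),
            "c": np.array([0.0, 0.0, 1.0]),
            "ab": np.array([1.0, 1.0, 0.0]),
        },
    )


@pytest.fixture
def toy_lexicon() -> CompoundLexicon:
    return CompoundLexicon([
        CompoundEntry("AB", "A", "B", 5, 100, 100),
        CompoundEntry("AC", "A", "C", 10, 100, 100),
        CompoundEntry("BA", "B", "A", 11, 100, 100),
        CompoundEntry("CB", "C", "B", 50, 100, 100),
    ])


def simulate_crossed(rng, n, q1, q2, beta, tau1, tau2, sigma, p=4):
    """Crossed-random-intercept data with known coefficients (test helper)."""
    g1 = rng.integers(0, q1, n)
    g2 = rng.integers(0, q2, n)
    X = rng.standard_normal((n, p))
    y = (
        beta[0]
        + X @ np.asarray(beta[1:])
        + rng.normal(0, tau1, q1)[g1]
        + rng.normal(0, tau2, q2)[g2]
        + rng.normal(0, sigma, n)
    )
    cols = {f"x{j + 1}": X[:, j] for j in range(p)}
    return pd.DataFrame({"y": y, **cols, "c1": g1, "c2": g2})
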