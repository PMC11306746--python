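import numpy as np
import pytest

from quboselect import GeneratorConfig, QuboMatrix, generate


@pytest.fixture(scope="session")
def default_table():
    """One default-config synthetic survey (751 x 40) plus ground truth."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_table():
    """A small table (300 x 12) solvable by exact enumeration in the sweep."""
    config = GeneratorConfig(
        n_respondents=300, n_relevant=3, n_redundant=2, n_noise=7, seed=11
    )
    return generate(config)


def random_qubo(p: int, rng: np.random.Generator) -> QuboMatrix:
    return QuboMatrix(np.triu(rng.normal(size=(p, p))))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
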