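import numpy as np
import pytest

from ngmda import (AssociationMatrix, RunConfig, SimilarityMatrix,
                   SyntheticConfig, generate_dataset)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default synthetic dataset with planted rank-4 structure."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture
def tiny_config():
    """A small, fast configuration for smoke/determinism tests."""
    return RunConfig(epochs=4, embed_dim=16, head_dim=16, nff_heads=2,
                     gff_heads=2, nff_layers=1, gff_layers=1)


@pytest.fixture
def small_assoc():
    rng = np.random.default_rng(3)
    values = (rng.random((6, 4)) < 0.4).astype(int)
    values[0, 0] = 1  # guarantee at least one positive
    return AssociationMatrix(values,
                             [f"d{i}" for i in range(6)],
                             [f"m{j}" for j in range(4)])


def random_similarity(rng, n, node_type):
    raw = rng.random((n, n))
    sym = 0.5 * (raw + raw.T)
    np.fill_diagonal(sym, 1.0)
    return SimilarityMatrix(sym, node_type)


@pytest.fixture
def small_similarities(small_assoc):
    rng = np.random.default_rng(4)
    return (random_similarity(rng, small_assoc.n_drugs, "drug"),
            random_similarity(rng, small_assoc.n_microbes, "microbe"))
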