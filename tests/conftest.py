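import numpy as np
import pytest

from symdelta.datamodel import MISSING, Dataset


def random_dataset(
    seed: int,
    n_variables: int = 5,
    n_samples: int = 200,
    n_bins: int = 3,
    missing_rate: float = 0.0,
) -> Dataset:
    """Random discrete dataset for property tests; reproducible by seed."""
    rng = np.random.default_rng(seed)
    matrix = rng.integers(0, n_bins, size=(n_samples, n_variables))
    if missing_rate > 0:
        matrix[rng.random(matrix.shape) < missing_rate] = MISSING
    names = [f"v{j}" for j in range(n_variables)]
    return Dataset.from_matrix(matrix, names, n_bins=[n_bins] * n_variables)


@pytest.fixture
def xor_dataset() -> Dataset:
    """Balanced noiseless XOR triple: X, Y uniform independent, Z = X^Y."""
    x = np.array([0, 0, 1, 1])
    y = np.array([0, 1, 0, 1])
    return Dataset.from_matrix(np.column_stack([x, y, x ^ y]), ["X", "Y", "Z"])


@pytest.fixture
def independent_triple() -> Dataset:
    """Exactly factorizing empirical joint over three binary variables."""
    rows = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])
    return Dataset.from_matrix(rows, ["A", "B", "C"])
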