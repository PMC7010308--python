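import numpy as np
import pytest

from woodwebs.core_data import InteractionMatrix


def im(array, trim=True) -> InteractionMatrix:
    """Wrap a plain array as an InteractionMatrix with generic labels."""
    array = np.asarray(array)
    hosts = [f"h{i:02d}" for i in range(array.shape[0])]
    beetles = [f"b{j:02d}" for j in range(array.shape[1])]
    return InteractionMatrix(hosts, beetles, array, trim=trim)


def random_trimmed_matrix(rng, max_rows=6, max_cols=6, max_count=5):
    """A random count matrix with no all-zero row or column."""
    while True:
        n_r = rng.integers(2, max_rows + 1)
        n_c = rng.integers(2, max_cols + 1)
        A = rng.integers(0, max_count + 1, size=(n_r, n_c))
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return A


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
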