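import numpy as np
import pandas as pd
import pytest

from shufflepower.countmatrix import CountMatrix


def make_count_matrix(counts, classes=None, n_per_group=None):
    """Build a CountMatrix from a 2-D array with CD/HFD split down the middle."""
    counts = np.asarray(counts)
    n_ann, n_samp = counts.shape
    if n_per_group is None:
        n_per_group = n_samp // 2
    ids = [f"ann_{i}" for i in range(n_ann)]
    samples = [f"CD_{j + 1}" for j in range(n_per_group)] + [
        f"HFD_{j + 1}" for j in range(n_samp - n_per_group)
    ]
    groups = pd.Series(["CD"] * n_per_group + ["HFD"] * (n_samp - n_per_group), index=samples)
    if classes is None:
        classes = ["gene"] * n_ann
    return CountMatrix(
        pd.DataFrame(counts, index=ids, columns=samples),
        groups,
        pd.Series(classes, index=ids),
    )


@pytest.fixture
def toy_cm():
    """10 annotations x (4+4) samples; 3 rows with raw mean 0.5."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(7, 8))
    low = np.zeros((3, 8), dtype=int)
    low[:, :4] = 1  # mean 0.5
    return make_count_matrix(np.vstack([counts, low]))


@pytest.fixture
def rng():
    return np.random.default_rng(20160721)
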