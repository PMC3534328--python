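import numpy as np
import pytest

from aflpselect import Hierarchy, MarkerMatrix, ReplicateSet

NA = np.nan


def make_matrix(rows, sample_ids=None, locus_ids=None):
    """Small-matrix helper: rows is a list of per-sample call lists."""
    arr = np.array(rows, dtype=float)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(arr.shape[0])]
    locus_ids = locus_ids or [f"L{j + 1}" for j in range(arr.shape[1])]
    return MarkerMatrix(arr, tuple(sample_ids), tuple(locus_ids))


def random_matrix_with_pairs(rng, n_ind=5, n_loci=8, n_pairs=2, missing_rate=0.15):
    """Random 0/1/NA matrix whose first ``n_pairs`` individuals are replicated."""
    n_rows = n_ind + n_pairs
    calls = (rng.random((n_rows, n_loci)) < 0.4).astype(float)
    calls[rng.random((n_rows, n_loci)) < missing_rate] = np.nan
    sample_ids = [f"i{k}" for k in range(n_ind)] + [f"i{k}r" for k in range(n_pairs)]
    m = MarkerMatrix(calls, tuple(sample_ids), tuple(f"L{j}" for j in range(n_loci)))
    reps = ReplicateSet(tuple((f"i{k}", f"i{k}r") for k in range(n_pairs)))
    return m, reps


@pytest.fixture
def tiny_matrix():
    # 4 individuals + 2 replicate rows, 4 loci, with targeted missingness
    return make_matrix(
        [
            [1, 0, 1, 0],   # i0
            [0, 0, 1, 1],   # i1
            [1, 1, NA, 0],  # i2
            [0, 1, 0, NA],  # i3
            [1, 0, 0, 0],   # i0r (mismatch at L3)
            [0, 1, 1, 1],   # i1r (mismatch at L2)
        ],
        sample_ids=["i0", "i1", "i2", "i3", "i0r", "i1r"],
    )


@pytest.fixture
def tiny_reps():
    return ReplicateSet((("i0", "i0r"), ("i1", "i1r")))


@pytest.fixture
def balanced_hierarchy():
    # 2 groups x 2 populations x 2 samples
    return Hierarchy(
        {
            "a1": ("pA", "g1"),
            "a2": ("pA", "g1"),
            "b1": ("pB", "g1"),
            "b2": ("pB", "g1"),
            "c1": ("pC", "g2"),
            "c2": ("pC", "g2"),
            "d1": ("pD", "g2"),
            "d2": ("pD", "g2"),
        }
    )
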