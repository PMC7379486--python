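import numpy as np
import pandas as pd
import pytest

from fibromod import ExpressionDataset, GeneSet, RankedList


@pytest.fixture
def small_two_class():
    """Six genes x six samples, three control + three case, fixed values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(size=(6, 6)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(6)],
    )
    return ExpressionDataset(values, labels=pd.Series([0, 0, 0, 1, 1, 1]))


@pytest.fixture
def four_gene_list():
    """The hand-worked N=4 ranked list with scores 4, 3, 2, 1."""
    return RankedList(
        genes=("A", "B", "C", "D"),
        scores=np.array([4.0, 3.0, 2.0, 1.0]),
        order="descending",
    )


def random_instance(rng, n_max=50):
    """A random (ranked list, hit mask) pair for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    scores = np.sort(rng.normal(size=n))[::-1]
    n_h = int(rng.integers(1, n))
    hit_idx = rng.choice(n, size=n_h, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[hit_idx] = True
    genes = tuple(f"G{i:03d}" for i in range(n))
    ranked = RankedList(genes=genes, scores=scores, order="descending")
    gene_set = GeneSet.from_iterable("S", [genes[i] for i in np.flatnonzero(mask)])
    return ranked, gene_set, mask
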