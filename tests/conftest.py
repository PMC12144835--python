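"""Shared fixtures and independent brute-force oracles for the test-suite."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings

from bigpicc.matrix import NORMAL, TUMOR, MutationMatrix

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


# -- independent oracles (kept free of the package's implementations) -----


def all_set_partitions(items):
    """Enumerate every partition of a finite set (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_cpm(D, partition, gamma):
    """Bipartite CPM quality straight from the incidence matrix.

    ``partition`` is an iterable of (gene_indices, sample_indices) pairs.
    """
    q = 0.0
    for genes, samples in partition:
        genes, samples = list(genes), list(samples)
        e = D[np.ix_(genes, samples)].sum() if genes and samples else 0
        q += e - gamma * len(genes) * len(samples)
    return float(q)


def exact_min_cover_size(target, covers):
    """Smallest number of covers whose union is the target (brute force)."""
    target = frozenset(target)
    if not target:
        return 0
    covers = [frozenset(c) & target for c in covers]
    for size in range(1, len(covers) + 1):
        for combo in combinations(covers, size):
            if frozenset().union(*combo) == target:
                return size
    raise ValueError("target not coverable")


# -- fixtures --------------------------------------------------------------


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples (2 tumor, 2 normal) with known joint mutations."""
    data = np.array(
        [
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return MutationMatrix(
        ["gA", "gB", "gC"],
        ["t1", "t2", "n1", "n2"],
        [TUMOR, TUMOR, NORMAL, NORMAL],
        data,
    )


@pytest.fixture
def random_matrix_factory():
    """Seeded random binary matrices with a tumor/normal column split."""

    def make(n_genes, n_samples, n_tumor, density, seed):
        rng = np.random.default_rng(seed)
        data = (rng.random((n_genes, n_samples)) < density).astype(np.uint8)
        labels = [TUMOR] * n_tumor + [NORMAL] * (n_samples - n_tumor)
        return MutationMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(n_samples)],
            labels,
            data,
        )

    return make
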