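import numpy as np
import pytest

from faime.io import ExpressionMatrix, GeneSetCollection, SampleGroups


@pytest.fixture
def tiny_expr():
    """4 genes x 2 samples, no ties, hand-checkable."""
    return ExpressionMatrix(
        ["g1", "g2", "g3", "g4"],
        ["s1", "s2"],
        np.array([[10.0, 1.0], [8.0, 2.0], [5.0, 9.0], [2.0, 4.0]]),
    )


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        "toy",
        {"top": frozenset({"g1", "g2"}), "bottom": frozenset({"g3", "g4"})},
    )


@pytest.fixture
def random_instance():
    """Factory for random small scoring instances."""

    def make(rng, n_genes=None, n_samples=None, n_sets=None):
        n_genes = n_genes or int(rng.integers(5, 26))
        n_samples = n_samples or int(rng.integers(2, 11))
        n_sets = n_sets or int(rng.integers(2, 9))
        genes = [f"g{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, n_samples))
        sets = {}
        for k in range(n_sets):
            size = int(rng.integers(1, n_genes))  # strictly below universe
            sets[f"m{k}"] = frozenset(rng.choice(genes, size, replace=False))
        expr = ExpressionMatrix(genes, [f"s{j}" for j in range(n_samples)], values)
        coll = GeneSetCollection("rand", sets)
        return expr, coll

    return make


@pytest.fixture
def two_group_labels():
    def make(samples, n_first, first="tumor", second="normal"):
        return SampleGroups(
            {s: (first if i < n_first else second) for i, s in enumerate(samples)}
        )

    return make
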