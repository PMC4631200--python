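"""Shared fixtures: small ground-truthed synthetic screens."""

import pytest

from stresscreen.synthetic import TruthConfig, make_truth, matrix_from_truth


def screen_pairs(queries, targets):
    """Query x target crosses plus query x query doubles (identifiable
    combined-model design)."""
    crosses = [tuple(sorted((q, t))) for q in queries for t in targets if q != t]
    within = [
        tuple(sorted((a, b))) for i, a in enumerate(queries) for b in queries[i + 1 :]
    ]
    return sorted(set(crosses + within))


@pytest.fixture(scope="session")
def small_truth():
    """Ten genes, three stress conditions, default effect ranges."""
    genes = [f"g{i}" for i in range(10)]
    return make_truth(genes, ["heat", "KCl", "diamide"], TruthConfig(), seed=42)


@pytest.fixture(scope="session")
def small_screen(small_truth):
    """Noise-free expression matrix of the ten-gene screen with all doubles
    and the Msn2/4 triples."""
    genes = small_truth.genes
    pairs = screen_pairs(genes[:4], genes)
    matrix = matrix_from_truth(small_truth, pairs, include_triples=True, replicate_cv=0)
    return small_truth, pairs, matrix
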