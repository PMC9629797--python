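import numpy as np
import pytest

from netfas import (
    FeatureNetwork,
    FeatureSimilarityMatrix,
    MutationProfileSet,
)


@pytest.fixture
def path_abc() -> FeatureNetwork:
    """Path graph a-b-c."""
    return FeatureNetwork.from_edge_list([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle_pendant() -> FeatureNetwork:
    """Triangle {1,2,3} with pendant vertex 4 attached to 3."""
    return FeatureNetwork.from_edge_list(
        [("1", "2"), ("1", "3"), ("2", "3"), ("3", "4")]
    )


@pytest.fixture
def five_vertex_base() -> FeatureSimilarityMatrix:
    """Five-vertex first-order fixture whose greatest-similarity paths
    realize the published products 1/72 (via 1-2-4) and 1/12 (via 1-5-4)."""
    s = np.zeros((5, 5))
    np.fill_diagonal(s, 1.0)
    for (i, j), v in {
        (0, 1): 1 / 8,
        (1, 3): 1 / 9,
        (0, 4): 1 / 3,
        (3, 4): 1 / 4,
        (1, 2): 1 / 10,
        (2, 3): 1 / 10,
    }.items():
        s[i, j] = s[j, i] = v
    return FeatureSimilarityMatrix(["1", "2", "3", "4", "5"], s)


@pytest.fixture
def toy_profiles() -> MutationProfileSet:
    """5 patients x 6 genes used by projection tests."""
    genes = ["g1", "g2", "g3", "g4", "g5", "g6"]
    samples = ["s1", "s2", "s3", "s4", "s5"]
    mat = np.array(
        [
            [1, 1, 1, 0, 0, 0],
            [1, 0, 1, 1, 0, 1],
            [0, 0, 0, 0, 1, 1],
            [1, 1, 1, 1, 1, 1],
            [0, 1, 0, 0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return MutationProfileSet(samples, genes, mat)


def random_connected_network(rng: np.random.Generator, n: int) -> FeatureNetwork:
    """Random connected graph on n vertices: spanning tree + extra edges."""
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.add((min(i, j), max(i, j)))
    return FeatureNetwork(vertex_ids=[f"v{i}" for i in range(n)], edges=edges)


def random_self_dominant_sims(
    rng: np.random.Generator, n: int
) -> FeatureSimilarityMatrix:
    """Random symmetric similarity matrix satisfying the metric axioms:
    built as the self-updated closure of a random connected network."""
    from netfas import compute_feature_similarity

    return compute_feature_similarity(random_connected_network(rng, n))
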