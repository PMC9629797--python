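"""Feature–feature similarity derived from the interaction network.

Two vertices sharing an edge get a *first-order proximity* of
``1 / |Edges(i) ∪ Edges(j)|`` — one over the number of distinct edges
incident to either endpoint. Pairs without an edge acquire a *high-order
proximity*: the maximum, over connecting paths, of the product of
first-order proximities along the path. The closure is computed with a
Floyd–Warshall recursion over the (max, ×) semiring:

    greatest(i, j, k+1) = max(greatest(i, j, k),
                              greatest(i, k+1, k) * greatest(k+1, j, k))

Finally each self-similarity s(i, i) is replaced by the sum of the vertex's
closure similarities to its direct neighbors, so that features in densely
connected regions are "more similar to themselves" than features in sparse
regions. The resulting matrix is a similarity metric: symmetric,
nonnegative, self-dominant (s(i,i) >= s(i,j)) and satisfying the similarity
triangle inequality s(i,j) + s(j,k) <= s(i,k) + s(j,j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import FeatureNetwork, InvalidInputError

logger = logging.getLogger(__name__)

_UNDERFLOW_FLOOR = 1e-300
_SYM_TOL = 1e-12


@dataclass
class FeatureSimilarityMatrix:
    """Dense symmetric matrix of pairwise feature similarities.

    ``self_updated`` records whether the diagonal has been replaced by the
    neighbor-sum self-similarity (after which the matrix is a similarity
    metric for non-isolated vertices).
    """

    vertex_ids: list[str]
    values: np.ndarray
    self_updated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.vertex_ids)
        if v.shape != (n, n):
            raise InvalidInputError(
                f"matrix shape {v.shape} does not match {n} vertex ids"
            )
        if not np.allclose(v, v.T, rtol=_SYM_TOL, atol=_SYM_TOL):
            raise InvalidInputError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise InvalidInputError("similarity values must lie in [0, 1]")
        self.values = v

    def index_of(self, vertex_id: str) -> int:
        return self.vertex_ids.index(vertex_id)


def first_order_proximity(network: FeatureNetwork) -> FeatureSimilarityMatrix:
    """First-order proximity matrix of a feature network.

    For adjacent vertices ``|Edges(i) ∪ Edges(j)| = deg(i) + deg(j) - 1``
    (the shared edge is counted once). Non-adjacent distinct pairs are 0;
    the diagonal is provisionally 1, to be overwritten by
    :func:`self_similarity_update`.
    """
    if network.n_vertices == 0:
        raise InvalidInputError("empty network")
    if not network.edges:
        raise InvalidInputError("network has no edges")
    n = network.n_vertices
    deg = network.degrees()
    s = np.zeros((n, n), dtype=float)
    for i, j in network.edges:
        s[i, j] = s[j, i] = 1.0 / (deg[i] + deg[j] - 1)
    np.fill_diagonal(s, 1.0)
    return FeatureSimilarityMatrix(list(network.vertex_ids), s, self_updated=False)


def greatest_similarity_all_pairs(
    base: FeatureSimilarityMatrix, max_intermediate: int | str = "all"
) -> FeatureSimilarityMatrix:
    """Max-product path closure of a first-order proximity matrix.

    Entry (i, j) of the result is the maximum over paths from i to j —
    restricted to intermediate vertices ``{0 .. max_intermediate-1}`` in
    input order — of the product of base values along the path. Since every
    factor is <= 1, revisiting a vertex never helps, so the closure equals
    the maximum over simple paths. The diagonal is left untouched.
    """
    n = len(base.vertex_ids)
    if max_intermediate == "all":
        k_max = n
    else:
        k_max = int(max_intermediate)
        if not (0 <= k_max <= n):
            raise InvalidInputError(
                f"max_intermediate {k_max} outside [0, {n}]"
            )
    s = base.values.copy()
    diag = np.diag(s).copy()
    for k in range(k_max):
        np.maximum(s, np.outer(s[:, k], s[k, :]), out=s)
        np.fill_diagonal(s, diag)
    tiny = (s < _UNDERFLOW_FLOOR) & (s > 0)
    if tiny.any():
        logger.warning("flushing %d underflowed path products to 0", tiny.sum())
        s[tiny] = 0.0
    return FeatureSimilarityMatrix(
        list(base.vertex_ids), s, self_updated=base.self_updated
    )


def self_similarity_update(
    closure: FeatureSimilarityMatrix, network: FeatureNetwork
) -> FeatureSimilarityMatrix:
    """Replace each diagonal entry by the sum of closure similarities to
    the vertex's direct neighbors.

    Isolated vertices get self-similarity 0 (empty sum); the stratification
    pipeline drops degree-0 features before profiles ever reach the
    alignment, so the metric axioms hold on every feature actually used.
    """
    if list(closure.vertex_ids) != list(network.vertex_ids):
        raise InvalidInputError("closure and network vertex sets differ")
    s = closure.values.copy()
    adj = network.adjacency()
    diag = np.asarray(adj.multiply(s).sum(axis=1)).ravel()
    np.fill_diagonal(s, diag)
    return FeatureSimilarityMatrix(list(closure.vertex_ids), s, self_updated=True)


def compute_feature_similarity(network: FeatureNetwork) -> FeatureSimilarityMatrix:
    """First-order proximity → full max-product closure → self-update."""
    base = first_order_proximity(network)
    closure = greatest_similarity_all_pairs(base, "all")
    return self_similarity_update(closure, network)


def knn_sparsify(network: FeatureNetwork, neighbor_count: int = 11) -> FeatureNetwork:
    """Keep, for each vertex, edges to its ``neighbor_count`` most
    influential neighbors; an edge survives if either endpoint selects it.

    Influence ranks neighbors by edge weight (descending), breaking ties by
    neighbor degree (higher first) then lexicographic vertex id — a
    self-contained stand-in for propagation-based influence distances.
    """
    if neighbor_count < 1:
        raise InvalidInputError("neighbor_count must be >= 1")
    deg = network.degrees()
    inc: dict[int, list[tuple[int, int]]] = {i: [] for i in range(network.n_vertices)}
    for e in network.edges:
        i, j = e
        inc[i].append(e)
        inc[j].append(e)
    kept: set[tuple[int, int]] = set()
    for v, inc_edges in inc.items():
        def rank(e: tuple[int, int]):
            u = e[1] if e[0] == v else e[0]
            return (
                -network.weights.get(e, 1.0),
                -deg[u],
                network.vertex_ids[u],
            )

        for e in sorted(inc_edges, key=rank)[:neighbor_count]:
            kept.add(e)
    return FeatureNetwork(
        vertex_ids=list(network.vertex_ids),
        edges=kept,
        weights={e: w for e, w in network.weights.items() if e in kept},
        communities=network.communities,
    )
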