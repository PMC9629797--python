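"""Feature interaction network: undirected graph over features (genes).

Vertices are features; an edge encodes relevance between two features.
Edges are unordered, self-loops and duplicates are rejected, and each edge
may carry a positive weight (default 1.0 when none is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse


class InvalidInputError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class FeatureNetwork:
    """Undirected feature graph.

    Parameters
    ----------
    vertex_ids
        Unique feature identifiers; position defines the vertex index.
    edges
        Unordered vertex-index pairs, stored canonically as ``(i, j)`` with
        ``i < j``.
    weights
        Optional positive weight per canonical edge. Weights never enter
        the structural proximity of the similarity computation; they only
        rank neighbors during k-nearest-neighbor sparsification.
    communities
        Optional planted community structure (lists of vertex indices),
        attached by the synthetic-cohort generator.
    """

    vertex_ids: list[str]
    edges: set[tuple[int, int]]
    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    communities: list[list[int]] | None = None

    def __post_init__(self) -> None:
        n = len(self.vertex_ids)
        if len(set(self.vertex_ids)) != n:
            raise InvalidInputError("vertex identifiers must be unique")
        canon: set[tuple[int, int]] = set()
        for e in self.edges:
            i, j = e
            if i == j:
                raise InvalidInputError(f"self-loop at vertex index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidInputError(f"edge {e} references undeclared vertex")
            canon.add((min(i, j), max(i, j)))
        if len(canon) != len(self.edges):
            raise InvalidInputError("duplicate (or reversed-duplicate) edges")
        self.edges = canon
        self.weights = {
            (min(i, j), max(i, j)): float(w) for (i, j), w in self.weights.items()
        }
        for e, w in self.weights.items():
            if e not in self.edges:
                raise InvalidInputError(f"weight given for non-edge {e}")
            if w <= 0:
                raise InvalidInputError(f"non-positive weight on edge {e}")
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edge_list(
        cls,
        pairs: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]],
        weights: Mapping[tuple[str, str], float] | None = None,
        vertex_ids: Sequence[str] | None = None,
    ) -> "FeatureNetwork":
        """Build a network from ``(u, v)`` or ``(u, v, w)`` identifier pairs.

        Duplicate and reversed edges are merged; when weights collide the
        maximum is kept. Extra isolated vertices may be declared through
        ``vertex_ids``.
        """
        ids: list[str] = list(vertex_ids) if vertex_ids is not None else []
        seen = set(ids)
        raw: list[tuple[str, str, float | None]] = []
        for rec in pairs:
            if len(rec) == 3:
                u, v, w = rec  # type: ignore[misc]
                w = float(w)
            else:
                u, v = rec  # type: ignore[misc]
                w = None
            if weights is not None and w is None:
                w = weights.get((u, v), weights.get((v, u)))
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    ids.append(x)
            raw.append((u, v, w))
        index = {v: i for i, v in enumerate(ids)}
        edges: set[tuple[int, int]] = set()
        wmap: dict[tuple[int, int], float] = {}
        for u, v, w in raw:
            if u == v:
                raise InvalidInputError(f"self-loop on {u!r}")
            e = (min(index[u], index[v]), max(index[u], index[v]))
            edges.add(e)
            if w is not None:
                wmap[e] = max(w, wmap.get(e, w))
        return cls(vertex_ids=ids, edges=edges, weights=wmap)

    # -- views -------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, vertex_id: str) -> int:
        return self._index[vertex_id]

    def __contains__(self, vertex_id: str) -> bool:
        return vertex_id in self._index

    def edge_weight(self, i: int, j: int) -> float:
        e = (min(i, j), max(i, j))
        if e not in self.edges:
            raise KeyError(e)
        return self.weights.get(e, 1.0)

    def adjacency(self, weighted: bool = False) -> sparse.csr_matrix:
        """Symmetric adjacency matrix (CSR)."""
        n = self.n_vertices
        if not self.edges:
            return sparse.csr_matrix((n, n))
        ii, jj, ww = [], [], []
        for (i, j) in self.edges:
            w = self.weights.get((i, j), 1.0) if weighted else 1.0
            ii += [i, j]
            jj += [j, i]
            ww += [w, w]
        return sparse.csr_matrix((ww, (ii, jj)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        for i, j in self.edges:
            g.add_edge(
                self.vertex_ids[i],
                self.vertex_ids[j],
                weight=self.weights.get((i, j), 1.0),
            )
        return g
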