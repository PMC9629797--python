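"""Feature Alignment Similarity (FAS).

A sample is a weighted feature profile: its present features, each carrying
weight 1/n. The FAS between profiles P and Q is the optimum of a
transportation problem over the bipartite graph of their features,

    s(P, Q) = max_{f >= 0}  sum_ij f_ij s(p_i, q_j)
    s.t.     sum_j f_ij = w(p_i)   for every i
             sum_i f_ij = w(q_j)   for every j

with ground similarities s(.,.) taken from a network-derived
:class:`~netfas.feature_similarity.FeatureSimilarityMatrix`. Dropping one
marginal constraint yields a cheap upper bound — each feature ships all of
its weight to its most similar counterpart — and the minimum of the two
one-sided bounds is a tighter combined bound, used to prune pairs before
solving the exact program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .feature_similarity import FeatureSimilarityMatrix
from .network import InvalidInputError

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-9


@dataclass
class WeightedFeatureProfile:
    """One sample's present features with their alignment weights."""

    feature_indices: np.ndarray
    weights: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.feature_indices, dtype=np.int64)
        w = np.asarray(self.weights, dtype=float)
        if idx.size == 0:
            raise InvalidInputError("empty profile")
        if idx.size != w.size:
            raise InvalidInputError("indices and weights differ in length")
        if len(np.unique(idx)) != idx.size:
            raise InvalidInputError("duplicate feature indices in profile")
        if (w <= 0).any():
            raise InvalidInputError("profile weights must be positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise InvalidInputError(f"profile weights sum to {w.sum()}, not 1")
        self.feature_indices = idx
        self.weights = w

    @classmethod
    def from_indices(
        cls, feature_indices: Sequence[int], sample_id: str | None = None
    ) -> "WeightedFeatureProfile":
        """Uniform weights 1/n over the n given features."""
        idx = np.asarray(sorted(feature_indices), dtype=np.int64)
        n = idx.size
        if n == 0:
            raise InvalidInputError("empty profile")
        return cls(idx, np.full(n, 1.0 / n), sample_id=sample_id)

    @property
    def size(self) -> int:
        return int(self.feature_indices.size)


@dataclass
class AlignmentResult:
    """Outcome of one profile-pair alignment.

    ``flow[i, j]`` is the weight shipped from the i-th feature of the
    source profile to the j-th feature of the target profile; for exact
    solutions it satisfies both marginal constraints.
    """

    similarity: float
    flow: np.ndarray
    status: Literal["exact", "relaxed_P", "relaxed_Q", "combined"]


def _check_inputs(
    p: WeightedFeatureProfile, q: WeightedFeatureProfile, sims: FeatureSimilarityMatrix
) -> np.ndarray:
    n = len(sims.vertex_ids)
    for prof in (p, q):
        if prof.feature_indices.max() >= n or prof.feature_indices.min() < 0:
            raise InvalidInputError("profile feature index out of range")
    return sims.values[np.ix_(p.feature_indices, q.feature_indices)]


@lru_cache(maxsize=64)
def _transport_constraints(m: int, n: int):
    """Equality-constraint matrix of the m x n transportation polytope."""
    rows = sparse.kron(sparse.eye(m), np.ones((1, n)))
    cols = sparse.kron(np.ones((1, m)), sparse.eye(n))
    return sparse.vstack([rows, cols]).tocsc()


def fas_exact(
    p: WeightedFeatureProfile,
    q: WeightedFeatureProfile,
    sims: FeatureSimilarityMatrix,
) -> AlignmentResult:
    """Exact FAS: the transportation optimum with both marginals enforced.

    Solved as a linear program (HiGHS); maximization is expressed as
    minimization of the negated similarities. The optimal value is unique
    and deterministic; the returned flow is one optimal vertex.
    """
    s_sub = _check_inputs(p, q, sims)
    m, n = s_sub.shape
    res = linprog(
        -s_sub.ravel(),
        A_eq=_transport_constraints(m, n),
        b_eq=np.concatenate([p.weights, q.weights]),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - infeasibility is pre-checked
        raise InvalidInputError(f"transportation LP failed: {res.message}")
    flow = res.x.reshape(m, n)
    return AlignmentResult(similarity=float(-res.fun), flow=flow, status="exact")


def fas_relaxed_bound(
    p: WeightedFeatureProfile,
    q: WeightedFeatureProfile,
    sims: FeatureSimilarityMatrix,
    drop: Literal["target", "source"] = "target",
) -> AlignmentResult:
    """One-sided relaxation: an upper bound on the exact FAS.

    With the target marginal dropped, every source feature ships its whole
    weight to its most similar target feature (ties broken toward the
    lowest index), giving sum_i w(p_i) max_j s(p_i, q_j). Dropping the
    source marginal gives the symmetric quantity from q's side.
    """
    s_sub = _check_inputs(p, q, sims)
    m, n = s_sub.shape
    flow = np.zeros((m, n))
    if drop == "target":
        best = np.argmax(s_sub, axis=1)
        flow[np.arange(m), best] = p.weights
        value = float(np.dot(p.weights, s_sub[np.arange(m), best]))
        status = "relaxed_P"
    elif drop == "source":
        best = np.argmax(s_sub, axis=0)
        flow[best, np.arange(n)] = q.weights
        value = float(np.dot(q.weights, s_sub[best, np.arange(n)]))
        status = "relaxed_Q"
    else:
        raise InvalidInputError(f"unknown constraint to drop: {drop!r}")
    return AlignmentResult(similarity=value, flow=flow, status=status)


def fas_combined_bound(
    p: WeightedFeatureProfile,
    q: WeightedFeatureProfile,
    sims: FeatureSimilarityMatrix,
) -> float:
    """min of the two one-sided bounds; still an upper bound on exact FAS."""
    s_sub = _check_inputs(p, q, sims)
    b1 = float(np.dot(p.weights, s_sub.max(axis=1)))
    b2 = float(np.dot(q.weights, s_sub.max(axis=0)))
    return min(b1, b2)


def fas_self(p: WeightedFeatureProfile, sims: FeatureSimilarityMatrix) -> float:
    """FAS(P, P) = sum_i w(p_i) s(p_i, p_i) — the identity alignment,
    optimal whenever the similarity matrix is self-dominant."""
    diag = np.diag(sims.values)[p.feature_indices]
    return float(np.dot(p.weights, diag))


@dataclass
class SampleSimilarityMatrix:
    """Symmetric sample-by-sample similarity with identifiers."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise InvalidInputError("shape does not match sample ids")
        if not np.allclose(v, v.T, rtol=1e-9, atol=1e-12):
            raise InvalidInputError("sample similarity matrix must be symmetric")
        self.values = v


def pairwise_fas_matrix(
    profiles: Sequence[WeightedFeatureProfile],
    sims: FeatureSimilarityMatrix,
    mode: Literal["exact", "combined_bound", "prune"] = "prune",
    budget: int = 50,
) -> SampleSimilarityMatrix:
    """All-pairs FAS matrix over a cohort of profiles.

    ``exact`` solves the transportation program for every pair;
    ``combined_bound`` substitutes the cheap min-bound everywhere;
    ``prune`` computes bounds for all pairs, then solves exactly only each
    sample's ``budget`` highest-bounded partners (a pair is solved if
    either endpoint selects it), keeping the bound elsewhere. The diagonal
    is FAS(P, P) under the identity alignment.
    """
    mm = len(profiles)
    if mm < 2:
        raise InvalidInputError("need at least two profiles")
    ids = [
        prof.sample_id if prof.sample_id is not None else f"S{i}"
        for i, prof in enumerate(profiles)
    ]
    values = np.zeros((mm, mm))
    for i, prof in enumerate(profiles):
        values[i, i] = fas_self(prof, sims)

    if mode not in ("exact", "combined_bound", "prune"):
        raise InvalidInputError(f"unknown mode {mode!r}")

    if mode == "exact":
        for i in range(mm):
            for j in range(i + 1, mm):
                values[i, j] = values[j, i] = fas_exact(
                    profiles[i], profiles[j], sims
                ).similarity
        return SampleSimilarityMatrix(ids, values)

    bounds = np.zeros((mm, mm))
    for i in range(mm):
        for j in range(i + 1, mm):
            bounds[i, j] = bounds[j, i] = fas_combined_bound(
                profiles[i], profiles[j], sims
            )
    if mode == "combined_bound":
        values[~np.eye(mm, dtype=bool)] = bounds[~np.eye(mm, dtype=bool)]
        return SampleSimilarityMatrix(ids, values)

    # prune: exact only where the bound ranks in either endpoint's top-B
    selected: set[tuple[int, int]] = set()
    for i in range(mm):
        order = np.argsort(-bounds[i])
        picked = [j for j in order if j != i][:budget]
        for j in picked:
            selected.add((min(i, j), max(i, j)))
    logger.info(
        "prune mode: %d of %d pairs solved exactly", len(selected), mm * (mm - 1) // 2
    )
    values[~np.eye(mm, dtype=bool)] = bounds[~np.eye(mm, dtype=bool)]
    for i, j in selected:
        ex = fas_exact(profiles[i], profiles[j], sims).similarity
        values[i, j] = values[j, i] = ex
    return SampleSimilarityMatrix(ids, values)
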