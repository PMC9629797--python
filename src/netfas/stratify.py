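"""NetAP: network-based affinity propagation for patient stratification.

Pipeline: sparsify the gene network to each gene's most influential
neighbors, project patient mutation profiles onto the network (dropping
off-network genes and patients with too few surviving mutations), compute
the network-derived feature similarity, build the all-pairs FAS patient
similarity matrix, and cluster it with affinity propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from sklearn.cluster import AffinityPropagation

from .fas import SampleSimilarityMatrix, WeightedFeatureProfile, pairwise_fas_matrix
from .feature_similarity import (
    FeatureSimilarityMatrix,
    compute_feature_similarity,
    knn_sparsify,
)
from .network import FeatureNetwork, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class MutationProfileSet:
    """Binary patients-by-genes incidence matrix with identifiers."""

    sample_ids: list[str]
    feature_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise InvalidInputError("matrix shape does not match identifiers")
        if not np.isin(m, (0, 1)).all():
            raise InvalidInputError("mutation matrix must be binary")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InvalidInputError("duplicate feature ids")
        self.matrix = m.astype(np.uint8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class ClusteringConfig:
    """Knobs of the NetAP pipeline.

    damping is affinity propagation's message-damping factor lambda;
    target_k, when set, is reached by bisecting the shared preference;
    min_mutations and knn are the projection and sparsification defaults.
    """

    damping: float = 0.9
    target_k: int | None = None
    preference: float | None = None
    max_iterations: int = 2000
    convergence_window: int = 200
    min_mutations: int = 10
    knn: int = 11
    fas_mode: Literal["exact", "combined_bound", "prune"] = "prune"
    prune_budget: int = 50

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise InvalidInputError("damping must lie in [0.5, 1)")
        if self.target_k is not None and self.target_k < 2:
            raise InvalidInputError("target_k must be >= 2")


@dataclass
class ClusterAssignment:
    """A partition of samples with its exemplars."""

    sample_ids: list[str]
    labels: list[int]
    exemplars: list[str]
    achieved_k: int
    converged: bool = True
    provenance: dict = field(default_factory=dict)


def project_profiles(
    data: MutationProfileSet,
    network: FeatureNetwork,
    min_mutations: int = 10,
) -> MutationProfileSet:
    """Restrict profiles to network genes of degree >= 1, then drop
    patients left with fewer than ``min_mutations`` mutations."""
    deg = network.degrees()
    keep_cols = [
        j
        for j, g in enumerate(data.feature_ids)
        if g in network and deg[network.index_of(g)] >= 1
    ]
    logger.info(
        "projection: keeping %d/%d genes present in the network",
        len(keep_cols),
        data.n_features,
    )
    if not keep_cols:
        raise InvalidInputError("no profile gene appears in the network")
    sub = data.matrix[:, keep_cols]
    row_counts = sub.sum(axis=1)
    keep_rows = np.flatnonzero(row_counts >= min_mutations)
    logger.info(
        "projection: removing %d/%d patients with < %d surviving mutations",
        data.n_samples - keep_rows.size,
        data.n_samples,
        min_mutations,
    )
    if keep_rows.size == 0:
        raise InvalidInputError(
            f"no patient retains >= {min_mutations} on-network mutations"
        )
    return MutationProfileSet(
        sample_ids=[data.sample_ids[i] for i in keep_rows],
        feature_ids=[data.feature_ids[j] for j in keep_cols],
        matrix=sub[keep_rows],
    )


def profiles_to_weighted(
    data: MutationProfileSet, vertex_ids: Sequence[str] | None = None
) -> list[WeightedFeatureProfile]:
    """One uniformly weighted profile per sample.

    Feature indices refer to ``vertex_ids`` when given (the similarity
    matrix vertex set), otherwise to the profile set's own feature order.
    """
    if vertex_ids is None:
        col_to_vertex = np.arange(data.n_features)
    else:
        index = {v: i for i, v in enumerate(vertex_ids)}
        try:
            col_to_vertex = np.asarray([index[g] for g in data.feature_ids])
        except KeyError as e:
            raise InvalidInputError(f"feature {e.args[0]!r} not in vertex set")
    out = []
    for i, sid in enumerate(data.sample_ids):
        cols = np.flatnonzero(data.matrix[i])
        if cols.size == 0:
            raise InvalidInputError(f"sample {sid!r} has no mutations")
        out.append(
            WeightedFeatureProfile.from_indices(col_to_vertex[cols], sample_id=sid)
        )
    return out


def _run_ap(
    values: np.ndarray, preference: float, config: ClusteringConfig
) -> tuple[np.ndarray, np.ndarray, bool]:
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=config.damping,
        preference=preference,
        max_iter=config.max_iterations,
        convergence_iter=config.convergence_window,
        random_state=0,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap.fit(values)
    labels = ap.labels_
    centers = ap.cluster_centers_indices_
    converged = centers is not None and len(np.atleast_1d(centers)) > 0 and not (
        np.asarray(labels) == -1
    ).any()
    if not converged:
        labels = np.zeros(values.shape[0], dtype=int)
        centers = np.array([0])
    return np.asarray(labels), np.atleast_1d(np.asarray(centers)), converged


def affinity_propagation_cluster(
    similarity: SampleSimilarityMatrix, config: ClusteringConfig | None = None
) -> ClusterAssignment:
    """Affinity propagation on a precomputed similarity matrix.

    When ``target_k`` is set, the shared preference is bisected between the
    minimum and maximum off-diagonal similarity (lower preference, fewer
    exemplars) for at most 30 steps; the closest achievable cluster count
    is returned, with a warning if the exact K was not hit.
    """
    config = config or ClusteringConfig()
    values = np.asarray(similarity.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-9):
        raise InvalidInputError("similarity matrix must be symmetric")
    off = values[~np.eye(values.shape[0], dtype=bool)]

    if config.preference is not None:
        prefs = [config.preference]
    elif config.target_k is None:
        prefs = [float(np.median(off))]
    else:
        prefs = None

    if prefs is not None:
        labels, centers, converged = _run_ap(values, prefs[0], config)
    else:
        # lower preference -> fewer exemplars; the off-diagonal minimum is
        # often not low enough for small K, so widen the lower end first
        lo, hi = float(off.min()), float(off.max())
        span = max(hi - lo, 1e-12)
        best = None
        steps = 0
        for t in range(8):
            lab, cen, conv = _run_ap(values, lo, config)
            steps += 1
            k = len(np.unique(lab))
            gap = abs(k - config.target_k)
            if best is None or gap < best[0]:
                best = (gap, lab, cen, conv)
            if k <= config.target_k:
                break
            lo -= span * 2**t
        for _ in range(max(0, 30 - steps)):
            mid = 0.5 * (lo + hi)
            lab, cen, conv = _run_ap(values, mid, config)
            k = len(np.unique(lab))
            gap = abs(k - config.target_k)
            if best is None or gap < best[0]:
                best = (gap, lab, cen, conv)
            if k == config.target_k:
                break
            if k < config.target_k:
                lo = mid
            else:
                hi = mid
        gap, labels, centers, converged = best
        if gap != 0:
            logger.warning(
                "bisection reached k=%d, not the requested %d",
                len(np.unique(labels)),
                config.target_k,
            )

    # relabel clusters to consecutive ints in order of first appearance
    uniq, relabeled = np.unique(labels, return_inverse=True)
    order = {}
    final = np.empty_like(relabeled)
    nxt = 0
    for i, lab in enumerate(relabeled):
        if lab not in order:
            order[lab] = nxt
            nxt += 1
        final[i] = order[lab]
    exemplars = [similarity.sample_ids[int(c)] for c in centers]
    return ClusterAssignment(
        sample_ids=list(similarity.sample_ids),
        labels=[int(x) for x in final],
        exemplars=exemplars,
        achieved_k=int(len(np.unique(final))),
        converged=bool(converged),
    )


def netap(
    data: MutationProfileSet,
    network: FeatureNetwork,
    config: ClusteringConfig | None = None,
    feature_similarity: FeatureSimilarityMatrix | None = None,
) -> ClusterAssignment:
    """The full NetAP pipeline.

    knn-sparsify -> project profiles -> feature similarity (first-order,
    max-product closure, self-update) -> uniform weighted profiles ->
    all-pairs FAS -> affinity propagation. A precomputed
    ``feature_similarity`` (over the sparsified network's vertex set) may
    be supplied to amortize the closure across runs on the same network.
    """
    config = config or ClusteringConfig()
    sparse_net = knn_sparsify(network, config.knn)
    projected = project_profiles(data, sparse_net, config.min_mutations)
    if feature_similarity is None:
        feature_similarity = compute_feature_similarity(sparse_net)
    profiles = profiles_to_weighted(projected, feature_similarity.vertex_ids)
    patient_sim = pairwise_fas_matrix(
        profiles, feature_similarity, mode=config.fas_mode, budget=config.prune_budget
    )
    assignment = affinity_propagation_cluster(patient_sim, config)
    assignment.provenance = {
        "config": asdict(config),
        "n_samples_in": data.n_samples,
        "n_samples_clustered": len(assignment.sample_ids),
        "n_features_in": data.n_features,
        "n_features_projected": projected.n_features,
        "network_edges": network.n_edges,
        "sparsified_edges": sparse_net.n_edges,
    }
    return assignment
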