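import numpy as np
import pytest

from netfas import (
    FeatureSimilarityMatrix,
    InvalidInputError,
    WeightedFeatureProfile,
    fas_combined_bound,
    fas_exact,
    fas_relaxed_bound,
    fas_self,
    pairwise_fas_matrix,
)

from .conftest import random_self_dominant_sims


def transport_optimum_network_simplex(p, q, sims, scale=10**7) -> float:
    """Independent oracle: integer-scaled min-cost flow via network simplex.

    Supplies and costs are rounded to `scale` resolution; with profile
    weights 1/n the rounding error in the optimum is < 1e-5.
    """
    import networkx as nx

    s_sub = sims.values[np.ix_(p.feature_indices, q.feature_indices)]
    m, n = s_sub.shape
    sup = np.round(p.weights * scale).astype(np.int64)
    dem = np.round(q.weights * scale).astype(np.int64)
    sup[-1] += scale - sup.sum()  # fix rounding drift
    dem[-1] += scale - dem.sum()
    g = nx.DiGraph()
    smax = s_sub.max()
    cost = np.round((smax - s_sub) * scale).astype(np.int64)
    for i in range(m):
        g.add_node(("p", i), demand=-int(sup[i]))
    for j in range(n):
        g.add_node(("q", j), demand=int(dem[j]))
    for i in range(m):
        for j in range(n):
            g.add_edge(("p", i), ("q", j), weight=int(cost[i, j]))
    total_cost, flow = nx.network_simplex(g)
    value = 0.0
    for i in range(m):
        for j, f in flow[("p", i)].items():
            value += f / scale * s_sub[i, j[1]]
    return value


def random_instance(rng, n_vertices=12, max_side=6):
    sims = random_self_dominant_sims(rng, n_vertices)
    m = int(rng.integers(1, max_side + 1))
    n = int(rng.integers(1, max_side + 1))
    p = WeightedFeatureProfile.from_indices(
        rng.choice(n_vertices, size=m, replace=False)
    )
    q = WeightedFeatureProfile.from_indices(
        rng.choice(n_vertices, size=n, replace=False)
    )
    return p, q, sims


class TestProfiles:
    def test_uniform_weights(self):
        p = WeightedFeatureProfile.from_indices([3, 1, 7, 5])
        assert p.size == 4
        np.testing.assert_allclose(p.weights, 0.25)
        assert p.weights.sum() == pytest.approx(1.0)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(InvalidInputError):
            WeightedFeatureProfile.from_indices([])
        with pytest.raises(InvalidInputError):
            WeightedFeatureProfile(np.array([0, 0]), np.array([0.5, 0.5]))
        with pytest.raises(InvalidInputError):
            WeightedFeatureProfile(np.array([0, 1]), np.array([0.5, 0.6]))


class TestExactFas:
    def test_identical_profile_worked_example(self):
        """P = Q = {(a,1/3),(b,1/3),(c,1/3)} with unit self-similarities
        aligns each feature to itself: FAS = 1."""
        s = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sims = FeatureSimilarityMatrix(["a", "b", "c"], s, self_updated=True)
        p = WeightedFeatureProfile.from_indices([0, 1, 2])
        res = fas_exact(p, p, sims)
        assert res.similarity == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.flow.sum(axis=1), p.weights, atol=1e-7)
        np.testing.assert_allclose(res.flow.sum(axis=0), p.weights, atol=1e-7)

    def test_single_feature_profiles(self):
        rng = np.random.default_rng(0)
        sims = random_self_dominant_sims(rng, 6)
        p = WeightedFeatureProfile.from_indices([2])
        q = WeightedFeatureProfile.from_indices([4])
        res = fas_exact(p, q, sims)
        assert res.similarity == pytest.approx(sims.values[2, 4])
        assert res.flow[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_network_simplex_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        p, q, sims = random_instance(rng)
        got = fas_exact(p, q, sims).similarity
        expect = transport_optimum_network_simplex(p, q, sims)
        assert got == pytest.approx(expect, abs=2e-5)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            p, q, sims = random_instance(rng)
            res = fas_exact(p, q, sims)
            np.testing.assert_allclose(res.flow.sum(axis=1), p.weights, atol=1e-7)
            np.testing.assert_allclose(res.flow.sum(axis=0), q.weights, atol=1e-7)
            assert (res.flow >= -1e-12).all()
            assert res.similarity == pytest.approx(
                float(
                    (res.flow * sims.values[np.ix_(p.feature_indices, q.feature_indices)]).sum()
                ),
                abs=1e-9,
            )

    def test_index_out_of_range_rejected(self):
        s = np.array([[1.0, 0.2], [0.2, 1.0]])
        sims = FeatureSimilarityMatrix(["a", "b"], s, self_updated=True)
        p = WeightedFeatureProfile.from_indices([0, 5])
        q = WeightedFeatureProfile.from_indices([0])
        with pytest.raises(InvalidInputError):
            fas_exact(p, q, sims)


class TestRelaxedBounds:
    def test_single_target_bound_equals_exact(self):
        rng = np.random.default_rng(1)
        sims = random_self_dominant_sims(rng, 8)
        p = WeightedFeatureProfile.from_indices([0, 3])
        q = WeightedFeatureProfile.from_indices([5])
        b = fas_relaxed_bound(p, q, sims, drop="target")
        e = fas_exact(p, q, sims)
        assert b.similarity == pytest.approx(e.similarity, abs=1e-9)

    def test_identity_example_bound_is_one(self):
        s = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sims = FeatureSimilarityMatrix(["a", "b", "c"], s, self_updated=True)
        p = WeightedFeatureProfile.from_indices([0, 1, 2])
        assert fas_relaxed_bound(p, p, sims).similarity == pytest.approx(1.0)
        assert fas_combined_bound(p, p, sims) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_dominate_exact(self, seed):
        rng = np.random.default_rng(500 + seed)
        p, q, sims = random_instance(rng)
        exact = fas_exact(p, q, sims).similarity
        b1 = fas_relaxed_bound(p, q, sims, drop="target").similarity
        b2 = fas_relaxed_bound(p, q, sims, drop="source").similarity
        comb = fas_combined_bound(p, q, sims)
        assert b1 >= exact - 1e-9
        assert b2 >= exact - 1e-9
        assert comb >= exact - 1e-9
        assert comb <= min(b1, b2) + 1e-12
        assert comb <= 1.0 + 1e-9  # trivial both-constraints-dropped ceiling

    def test_strict_gap_exists(self):
        """Both sources prefer target c and both targets prefer source a;
        the capacity collisions make each one-sided relaxation (and hence
        the combined bound) strictly exceed the exact optimum."""
        #        a     b     c     d
        s = np.array(
            [
                [0.95, 0.0, 0.9, 0.7],
                [0.0, 0.95, 0.8, 0.1],
                [0.9, 0.8, 0.95, 0.0],
                [0.7, 0.1, 0.0, 0.95],
            ]
        )
        sims = FeatureSimilarityMatrix(["a", "b", "c", "d"], s, self_updated=True)
        p = WeightedFeatureProfile.from_indices([0, 1])  # {a, b}
        q = WeightedFeatureProfile.from_indices([2, 3])  # {c, d}
        b1 = fas_relaxed_bound(p, q, sims, drop="target").similarity
        b2 = fas_relaxed_bound(p, q, sims, drop="source").similarity
        exact = fas_exact(p, q, sims).similarity
        comb = fas_combined_bound(p, q, sims)
        assert b1 == pytest.approx(0.85)  # a->c, b->c
        assert b2 == pytest.approx(0.80)  # c<-a, d<-a
        assert exact == pytest.approx(0.75)  # a->d, b->c
        assert comb == pytest.approx(0.80)
        assert comb > exact + 1e-6

    def test_symmetric_input_combined_equals_exact(self):
        rng = np.random.default_rng(9)
        sims = random_self_dominant_sims(rng, 10)
        p = WeightedFeatureProfile.from_indices([1, 4, 7])
        assert fas_combined_bound(p, p, sims) == pytest.approx(
            fas_exact(p, p, sims).similarity, abs=1e-9
        )
        assert fas_self(p, sims) == pytest.approx(
            fas_exact(p, p, sims).similarity, abs=1e-9
        )


class TestFasMetricAxioms:
    def test_conditions_on_random_triples(self):
        """Exact FAS over a self-dominant similarity matrix is a similarity
        metric: symmetric, nonnegative, self-dominant, and satisfying
        s(P,Q) + s(Q,R) <= s(P,R) + s(Q,Q)."""
        rng = np.random.default_rng(77)
        sims = random_self_dominant_sims(rng, 14)
        for _ in range(60):
            profs = [
                WeightedFeatureProfile.from_indices(
                    rng.choice(14, size=int(rng.integers(1, 6)), replace=False)
                )
                for _ in range(3)
            ]
            P, Q, R = profs
            spq = fas_exact(P, Q, sims).similarity
            sqp = fas_exact(Q, P, sims).similarity
            assert spq == pytest.approx(sqp, abs=1e-8)
            assert spq >= -1e-12
            assert fas_self(P, sims) >= spq - 1e-8
            sqr = fas_exact(Q, R, sims).similarity
            spr = fas_exact(P, R, sims).similarity
            assert spq + sqr <= spr + fas_self(Q, sims) + 1e-8


class TestPairwiseMatrix:
    def _profiles(self, rng, sims, m=6):
        n = len(sims.vertex_ids)
        return [
            WeightedFeatureProfile.from_indices(
                rng.choice(n, size=int(rng.integers(2, 6)), replace=False),
                sample_id=f"s{i}",
            )
            for i in range(m)
        ]

    def test_identical_profiles_offdiag_equals_diag(self):
        rng = np.random.default_rng(3)
        sims = random_self_dominant_sims(rng, 10)
        p = WeightedFeatureProfile.from_indices([1, 3, 5], sample_id="a")
        q = WeightedFeatureProfile.from_indices([1, 3, 5], sample_id="b")
        mat = pairwise_fas_matrix([p, q], sims, mode="exact")
        assert mat.values[0, 1] == pytest.approx(mat.values[0, 0], abs=1e-8)

    def test_bound_mode_dominates_exact_mode(self):
        rng = np.random.default_rng(8)
        sims = random_self_dominant_sims(rng, 12)
        profs = self._profiles(rng, sims)
        exact = pairwise_fas_matrix(profs, sims, mode="exact").values
        bound = pairwise_fas_matrix(profs, sims, mode="combined_bound").values
        off = ~np.eye(len(profs), dtype=bool)
        assert (bound[off] >= exact[off] - 1e-9).all()

    def test_prune_mode_interpolates(self):
        rng = np.random.default_rng(21)
        sims = random_self_dominant_sims(rng, 12)
        profs = self._profiles(rng, sims, m=8)
        exact = pairwise_fas_matrix(profs, sims, mode="exact").values
        pruned = pairwise_fas_matrix(profs, sims, mode="prune", budget=2).values
        bound = pairwise_fas_matrix(profs, sims, mode="combined_bound").values
        assert (pruned >= exact - 1e-9).all()
        assert (pruned <= bound + 1e-9).all()
        full = pairwise_fas_matrix(profs, sims, mode="prune", budget=10).values
        np.testing.assert_allclose(full, exact, atol=1e-9)

    def test_condition4_on_exact_matrix(self):
        rng = np.random.default_rng(13)
        sims = random_self_dominant_sims(rng, 12)
        profs = self._profiles(rng, sims, m=5)
        v = pairwise_fas_matrix(profs, sims, mode="exact").values
        d = np.diag(v)
        lhs = v[:, :, None] + v.T[None, :, :]
        rhs = v[:, None, :] + d[None, :, None]
        assert (lhs <= rhs + 1e-8).all()

    def test_empty_list_rejected(self):
        rng = np.random.default_rng(2)
        sims = random_self_dominant_sims(rng, 6)
        with pytest.raises(InvalidInputError):
            pairwise_fas_matrix([], sims)
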