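import numpy as np
import pytest

from pocketatlas import (
    Clustering,
    DistanceMatrix,
    PocketTree,
    balance_to_size,
    cluster_single_linkage,
    cluster_split,
    tree_split,
    validate_split,
)
from pocketatlas.errors import EdgeNotFound, EmptyTest, IdMismatch


def _dm(rng, n):
    M = rng.uniform(0.1, 3.0, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return DistanceMatrix(ids=[f"p{i}" for i in range(n)], D=M)


def _singletons(n):
    return Clustering(ids=[f"p{i}" for i in range(n)],
                      labels=np.arange(n), t=0.0)


class TestClusterSplit:
    def test_singletons_exact_fraction(self):
        s = cluster_split(_singletons(10), 0.2, seed=4)
        assert len(s.test_ids) == 2
        assert len(s.train_ids) == 8
        assert s.method == "random"

    def test_giant_cluster_flagged_infeasible(self):
        C = Clustering(ids=[f"p{i}" for i in range(10)],
                       labels=np.array([0] * 9 + [1]), t=1.0)
        s = cluster_split(C, 0.2, seed=0)
        assert s.provenance["infeasible"]
        assert set(s.test_ids) | set(s.train_ids) == set(C.ids)

    def test_two_equal_clusters_half_each(self):
        C = Clustering(ids=[f"p{i}" for i in range(8)],
                       labels=np.array([0] * 4 + [1] * 4), t=1.0)
        s = cluster_split(C, 0.5, seed=1)
        assert len(s.test_ids) == 4 and len(s.train_ids) == 4

    def test_deterministic_per_seed(self):
        C = _singletons(20)
        s1 = cluster_split(C, 0.3, seed=7)
        s2 = cluster_split(C, 0.3, seed=7)
        assert s1.test_ids == s2.test_ids
        s3 = cluster_split(C, 0.3, seed=8)
        assert s1.test_ids != s3.test_ids

    def test_whole_clusters_never_straddle(self, rng):
        D = _dm(rng, 30)
        C = next(
            C for q in (0.2, 0.1, 0.05, 0.01)
            for C in [cluster_single_linkage(D, np.quantile(D.off_diagonal(), q))]
            if C.n_clusters >= 2
        )
        s = cluster_split(C, 0.25, seed=2)
        test = set(s.test_ids)
        for k in range(C.n_clusters):
            members = set(C.members(k))
            assert members <= test or not (members & test)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            cluster_split(_singletons(5), 1.2, seed=0)


class TestTreeSplit:
    def _setup(self):
        # path tree over 3 clusters of 2 pockets each
        C = Clustering(ids=[f"p{i}" for i in range(6)],
                       labels=np.array([0, 0, 1, 1, 2, 2]), t=1.0)
        tree = PocketTree(sizes={0: 2, 1: 2, 2: 2},
                          edges=[(0, 1, 1.0), (1, 2, 1.0)])
        return C, tree

    def test_branch_becomes_test(self):
        C, tree = self._setup()
        s = tree_split(tree, C, [(0, 1)])
        assert sorted(s.test_ids) == ["p2", "p3", "p4", "p5"]
        assert sorted(s.train_ids) == ["p0", "p1"]
        assert s.method == "tree"

    def test_no_cuts_is_empty_test(self):
        C, tree = self._setup()
        with pytest.raises(EmptyTest):
            tree_split(tree, C, [])

    def test_train_always_keeps_parent_side(self):
        """The directed cut keeps u's side in train, so repeated cuts can
        never empty the training set."""
        C, tree = self._setup()
        s = tree_split(tree, C, [(1, 0), (1, 2)])
        assert sorted(s.train_ids) == ["p2", "p3"]
        assert sorted(s.test_ids) == ["p0", "p1", "p4", "p5"]

    def test_sequential_cuts_on_shrinking_tree(self):
        C = Clustering(ids=[f"p{i}" for i in range(8)],
                       labels=np.array([0, 0, 1, 1, 2, 2, 3, 3]), t=1.0)
        tree = PocketTree(sizes={0: 2, 1: 2, 2: 2, 3: 2},
                          edges=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        s = tree_split(tree, C, [(2, 3), (1, 2)])
        assert sorted(s.test_ids) == ["p4", "p5", "p6", "p7"]

    def test_edge_gone_after_earlier_cut(self):
        C = Clustering(ids=[f"p{i}" for i in range(8)],
                       labels=np.array([0, 0, 1, 1, 2, 2, 3, 3]), t=1.0)
        tree = PocketTree(sizes={0: 2, 1: 2, 2: 2, 3: 2},
                          edges=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        with pytest.raises(EdgeNotFound):
            tree_split(tree, C, [(1, 2), (2, 3)])   # (2,3) left with the branch

    def test_no_cluster_straddles(self, rng):
        from pocketatlas import build_mst, cluster_min_distances

        D = _dm(rng, 24)
        C = cluster_single_linkage(D, 0.8)
        if C.n_clusters < 3:
            C = cluster_single_linkage(D, 0.4)
        CD = cluster_min_distances(D, C)
        tree = build_mst(CD, {k: int(v) for k, v in enumerate(C.sizes())})
        u, v, _w = tree.edges[0]
        s = tree_split(tree, C, [(u, v)])
        test = set(s.test_ids)
        for k in range(C.n_clusters):
            members = set(C.members(k))
            assert members <= test or not (members & test)


class TestBalanceToSize:
    def test_rebalances_into_band(self):
        # 10 singleton clusters, start with an oversized test side
        C = _singletons(20)
        s = cluster_split(C, 0.35, seed=1)
        b = balance_to_size(s, C, 0.20)
        assert 0.15 <= b.test_fraction <= 0.25
        assert not b.provenance["infeasible"]

    def test_already_within_band_unchanged(self):
        C = _singletons(10)
        s = cluster_split(C, 0.2, seed=1)
        b = balance_to_size(s, C, 0.2)
        assert sorted(b.test_ids) == sorted(s.test_ids)

    def test_two_clusters_infeasible_flagged(self):
        C = Clustering(ids=[f"p{i}" for i in range(10)],
                       labels=np.array([0] * 5 + [1] * 5), t=1.0)
        s = cluster_split(C, 0.5, seed=0)
        b = balance_to_size(s, C, 0.2)
        assert b.provenance["infeasible"]
        assert len(b.test_ids) in (5,)   # whole clusters only

    def test_never_splits_a_cluster(self):
        C = Clustering(ids=[f"p{i}" for i in range(12)],
                       labels=np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3]),
                       t=1.0)
        s = cluster_split(C, 0.5, seed=3)
        b = balance_to_size(s, C, 0.25)
        test = set(b.test_ids)
        for k in range(4):
            members = set(C.members(k))
            assert members <= test or not (members & test)


class TestValidateSplit:
    def test_cluster_split_has_zero_leakage_at_its_threshold(self, rng):
        """The separation guarantee transfers to the split: no train-test
        pair below the clustering threshold (50 random instances)."""
        for k in range(50):
            n = int(rng.integers(12, 60))
            D = _dm(rng, n)
            t = float(rng.uniform(0.3, 1.5))
            C = cluster_single_linkage(D, t)
            if C.n_clusters < 2:
                C = cluster_single_linkage(D, 0.2)
                t = 0.2
            s = cluster_split(C, 0.3, seed=k)
            rep = validate_split(s, D, t)
            assert rep.n_violating_pairs == 0
            assert rep.min_cross_distance >= t

    def test_random_split_of_tight_cluster_leaks(self, rng):
        n = 16
        M = rng.uniform(0.05, 0.2, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = DistanceMatrix(ids=[f"p{i}" for i in range(n)], D=M)
        s = cluster_split(_singletons(n), 0.25, seed=0)
        rep = validate_split(s, D, 1.0)
        assert rep.n_violating_pairs > 0
        assert rep.violating_examples

    def test_t_zero_never_violates(self, rng):
        D = _dm(rng, 10)
        s = cluster_split(_singletons(10), 0.3, seed=0)
        assert validate_split(s, D, 0.0).n_violating_pairs == 0

    def test_unknown_ids_rejected(self, rng):
        D = _dm(rng, 6)
        s = cluster_split(_singletons(10), 0.3, seed=0)
        with pytest.raises(IdMismatch):
            validate_split(s, D, 1.0)


class TestHardnessMonotonicity:
    def test_cross_split_min_distance_nondecreasing_in_t(self):
        """On planted-family data the expected minimum train-test distance
        grows with the clustering threshold."""
        from pocketatlas import (
            EmbedderSpec,
            TessellationParams,
            compute_interface_residues,
            embed_complex,
            generate_pocket_families,
            pairwise_distances,
            pool_pocket_embedding,
            threshold_from_largest_gap,
        )

        mins = {0.0: [], "t": []}
        for seed in range(5):
            fams = generate_pocket_families(
                n_superfamilies=2, families_per_superfamily=2,
                members_per_family=6, seed=40 + seed,
            )
            vecs = []
            for fm in fams:
                iface = compute_interface_residues(
                    fm.truth.complex, TessellationParams(6.0)
                )
                vecs.append(pool_pocket_embedding(
                    embed_complex(fm.truth.complex, EmbedderSpec(dim=32)), iface
                ))
            D = pairwise_distances(vecs)
            t = threshold_from_largest_gap(D)
            for key, thr in ((0.0, 0.0), ("t", t)):
                C = cluster_single_linkage(D, thr)
                s = cluster_split(C, 0.25, seed=seed)
                mins[key].append(validate_split(s, D, 0.0).min_cross_distance)
        assert np.mean(mins["t"]) > np.mean(mins[0.0])
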