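import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform

import ciliaprofile as cp
from ciliaprofile.profiling import (
    ciliated_position_sum,
    pairwise_distances,
    stratified_species_removal,
)

from _oracles import (
    all_leaf_orderings,
    dendrogram_partitions,
    merge_partitions,
    naive_average_linkage,
)


class TestPairwiseDistances:
    def test_euclidean_is_sqrt_hamming(self):
        matrix = cp.ProfileMatrix(
            ["g1", "g2"], ["s1", "s2", "s3"], np.array([[1, 0, 0], [0, 1, 0]])
        )
        d = pairwise_distances(matrix, "genes", "euclidean")
        assert d[0] == pytest.approx(np.sqrt(2))

    def test_identical_rows_have_zero_distance(self):
        matrix = cp.ProfileMatrix(
            ["g1", "g2"], ["s1", "s2"], np.array([[1, 0], [1, 0]])
        )
        assert pairwise_distances(matrix, "genes")[0] == 0

    def test_mean_squared_is_hamming_over_n(self):
        matrix = cp.ProfileMatrix(
            ["g1", "g2"], ["s1", "s2", "s3", "s4"],
            np.array([[1, 0, 0, 1], [0, 1, 0, 1]]),
        )
        d = pairwise_distances(matrix, "genes", "mean_squared")
        assert d[0] == pytest.approx(2 / 4)

    @pytest.mark.parametrize("metric", ["euclidean", "mean_squared"])
    def test_matches_double_loop_oracle(self, metric, rng):
        values = rng.integers(0, 2, size=(6, 10))
        matrix = cp.ProfileMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(10)], values
        )
        got = squareform(pairwise_distances(matrix, "genes", metric))
        for i in range(6):
            for j in range(6):
                hamming = int(np.sum(values[i] != values[j]))
                expected = np.sqrt(hamming) if metric == "euclidean" else hamming / 10
                assert got[i, j] == pytest.approx(expected)

    def test_single_item_axis_rejected(self):
        matrix = cp.ProfileMatrix(["g1"], ["s1", "s2"], np.array([[1, 0]]))
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_distances(matrix, "genes")


class TestAverageLinkage:
    def test_three_point_hand_example(self):
        # d(AB)=1, d(AC)=d(BC)=4: AB merge at 1, then C joins at 4
        d = np.array([1.0, 4.0, 4.0])
        tree = cp.average_linkage(d, ["A", "B", "C"])
        assert tree.merges[0][:2] in ((0, 1), (1, 0))
        assert tree.merges[0][2] == pytest.approx(1.0)
        assert tree.merges[1][2] == pytest.approx(4.0)

    def test_identical_points_merge_at_zero(self):
        d = np.array([0.0, 3.0, 3.0])
        tree = cp.average_linkage(d, ["A", "B", "C"])
        assert tree.merges[0][2] == 0.0

    def test_matches_naive_oracle_on_random_instances(self, rng):
        # continuous random distances are almost surely tie-free, so the
        # merge partition sequence is unique and comparable
        for _ in range(30):
            n = int(rng.integers(3, 9))
            d = rng.uniform(0.5, 10.0, size=n * (n - 1) // 2)
            tree = cp.average_linkage(d)
            expected = merge_partitions(naive_average_linkage(d))
            got = dendrogram_partitions(tree)
            for (set_a, h_a), (set_b, h_b) in zip(expected, got):
                assert set_a == set_b
                assert h_a == pytest.approx(h_b)

    def test_nan_distance_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            cp.average_linkage(np.array([1.0, np.nan, 2.0]))

    def test_heights_monotone_rootward(self, rng):
        d = rng.uniform(0, 5, size=45)  # 10 items
        tree = cp.average_linkage(d)  # Dendrogram validates monotonicity
        heights = [h for _, _, h in tree.merges]
        # merge list from average linkage is sorted by height
        assert heights == sorted(heights)


class TestCiliatedLeftOrdering:
    def annotations(self, flags):
        return {
            f"s{i}": cp.SpeciesAnnotation(
                f"s{i}", "opisthokonta" if f else "amoebozoa", f, False
            )
            for i, f in enumerate(flags)
        }

    def tree_from_merges(self, merges, n):
        return cp.Dendrogram(merges=list(merges), leaf_ids=[f"s{i}" for i in range(n)])

    def test_ciliated_clade_moves_left(self):
        # ((c,n),(c,c)): the all-ciliated right clade must come first
        tree = self.tree_from_merges([(0, 1, 1.0), (2, 3, 1.0), (4, 5, 2.0)], 4)
        ann = self.annotations([True, False, True, True])
        order = cp.order_leaves_ciliated_left(tree, ann)
        assert order[:2] == ["s2", "s3"]

    def test_all_ciliated_preserves_input_order(self):
        tree = self.tree_from_merges([(0, 1, 1.0), (2, 3, 1.0), (4, 5, 2.0)], 4)
        ann = self.annotations([True, True, True, True])
        assert cp.order_leaves_ciliated_left(tree, ann) == ["s0", "s1", "s2", "s3"]

    def test_single_species_unchanged(self):
        tree = self.tree_from_merges([], 1)
        ann = self.annotations([True])
        assert cp.order_leaves_ciliated_left(tree, ann) == ["s0"]

    def test_unannotated_leaf_rejected(self):
        tree = self.tree_from_merges([(0, 1, 1.0)], 2)
        with pytest.raises(ValueError, match="unannotated"):
            cp.order_leaves_ciliated_left(tree, {})

    def test_exhaustively_optimal_on_small_trees(self, rng):
        # over random trees <= 8 leaves and random ciliated flags, the
        # greedy ordering achieves the minimum ciliated-position sum among
        # all 2^(n-1) child orderings, and is a permutation of the leaves
        for _ in range(25):
            n = int(rng.integers(2, 9))
            d = rng.uniform(0.5, 10.0, size=n * (n - 1) // 2)
            tree = cp.average_linkage(d, [f"s{i}" for i in range(n)])
            flags = [bool(rng.integers(2)) for _ in range(n)]
            ann = self.annotations(flags)
            original_merges = list(tree.merges)
            order = cp.order_leaves_ciliated_left(tree, ann)
            assert sorted(order) == sorted(tree.leaf_ids)
            objective = ciliated_position_sum(order, ann)
            best = min(
                ciliated_position_sum([f"s{i}" for i in perm], ann)
                for perm in all_leaf_orderings(original_merges, n)
            )
            assert objective == best


class TestSeedClusterExtraction:
    @pytest.fixture
    def planted(self, small_sim):
        matrix, truth, annotations = small_sim
        gene_tree, _ = cp.cluster_matrix(matrix)
        return matrix, truth, gene_tree

    def test_elbow_recovers_planted_module_exactly(self, planted):
        matrix, truth, gene_tree = planted
        result = cp.extract_seed_cluster(gene_tree, matrix, "CIL0001", "elbow")
        assert result.member_gene_ids == truth.module_members("cil")

    def test_cut_below_first_merge_returns_seed_alone(self, planted):
        matrix, _, gene_tree = planted
        result = cp.extract_seed_cluster(
            gene_tree, matrix, "CIL0001", "fixed_height", -1.0
        )
        assert result.member_gene_ids == {"CIL0001"}
        assert result.seed_gene_id == "CIL0001"

    def test_target_size_returns_minimal_clade_at_least_k(self, planted):
        matrix, truth, gene_tree = planted
        k = len(truth.module_members("cil"))
        result = cp.extract_seed_cluster(
            gene_tree, matrix, "CIL0001", "target_size", k
        )
        assert result.size >= k
        # every strictly smaller seed clade must be below the target
        smaller = [s for _, s in result.growth_trace if s < result.size]
        assert all(s < k for s in smaller)

    def test_growth_trace_sizes_nondecreasing(self, planted):
        matrix, _, gene_tree = planted
        result = cp.extract_seed_cluster(gene_tree, matrix, "CIL0001", "elbow")
        sizes = [s for _, s in result.growth_trace]
        assert sizes == sorted(sizes)

    def test_unknown_seed_rejected(self, planted):
        matrix, _, gene_tree = planted
        with pytest.raises(KeyError, match="NOSUCH"):
            cp.extract_seed_cluster(gene_tree, matrix, "NOSUCH", "elbow")


class TestRobustnessSubsampling:
    def test_fraction_zero_retains_full_cluster(self, small_sim):
        matrix, truth, annotations = small_sim
        retained, genes = cp.robustness_subsample(
            matrix, annotations, "CIL0001", fraction=0.0
        )
        assert genes == truth.module_members("cil")
        assert retained == len(truth.module_members("cil"))

    def test_half_removal_noise_free_retains_planted_module(self, small_sim):
        matrix, truth, annotations = small_sim
        retained, genes = cp.robustness_subsample(
            matrix, annotations, "CIL0001", fraction=0.5, rng_seed=11
        )
        assert genes == truth.module_members("cil")

    def test_stratified_removal_keeps_every_group(self, toy_annotations, rng):
        keep = stratified_species_removal(toy_annotations, 0.4, rng)
        groups_before = {a.major_group for a in toy_annotations}
        kept_groups = {
            a.major_group for a in toy_annotations if a.species_id in keep
        }
        assert kept_groups == groups_before

    def test_fraction_wiping_a_group_rejected(self, toy_annotations, rng):
        # 0.9 of a 2-member group rounds to removing both genomes
        with pytest.raises(ValueError, match="group"):
            stratified_species_removal(toy_annotations, 0.9, rng)
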