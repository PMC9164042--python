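import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsafpipe import (
    LadderRules,
    RunKey,
    ValidationError,
    cluster,
    entanglement,
    exact_critical_value,
    exclusive_intersections,
    list_dissimilarity,
    protocol_variability_comparison,
    rank_sum_exact,
    run_ladder,
    variability_matrix,
)
from nsafpipe.set_comparison import design_leaf_order, stage_run_lists, untangle_leaf_order

from _oracles import oracle_ranksum

small_sets = st.sets(st.sampled_from("abcdefghij"), max_size=6)


class TestExclusiveIntersections:
    def test_two_overlapping_sets(self):
        df = exclusive_intersections({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
        rows = {row.combination: row.exclusive_count for row in df.itertuples()}
        assert rows == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_identical_sets_collapse_to_one_row(self):
        sets = {d: {"x", "y", "z"} for d in range(1, 7)}
        df = exclusive_intersections(sets)
        assert len(df) == 1
        assert df.iloc[0]["combination"] == tuple(range(1, 7))
        assert df.iloc[0]["exclusive_count"] == 3

    def test_no_sets_rejected(self):
        with pytest.raises(ValidationError):
            exclusive_intersections({})

    @given(st.dictionaries(st.sampled_from("ABCDE"), small_sets, min_size=1, max_size=5))
    def test_counts_partition_the_union(self, named):
        df = exclusive_intersections(named)
        union = set().union(*named.values())
        assert df["exclusive_count"].sum() == len(union)
        members = [m for row in df["members"] for m in row]
        assert len(members) == len(set(members)) == len(union)


class TestListDissimilarity:
    def test_identical_and_disjoint(self):
        assert list_dissimilarity({"a"}, {"a"}) == 0.0
        assert list_dissimilarity({"a"}, {"b"}) == 1.0

    def test_half_overlap(self):
        assert list_dissimilarity({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            list_dissimilarity(set(), set())

    @given(small_sets, small_sets, small_sets)
    def test_metric_axioms(self, a, b, c):
        sets = [s for s in (a, b, c)]
        if not any(sets[i] | sets[j] for i, j in itertools.combinations(range(3), 2)):
            return
        for x, y in itertools.combinations(range(3), 2):
            if sets[x] | sets[y]:
                assert list_dissimilarity(sets[x], sets[y]) == list_dissimilarity(sets[y], sets[x])
        if a and b and c:
            assert (list_dissimilarity(a, c)
                    <= list_dissimilarity(a, b) + list_dissimilarity(b, c) + 1e-12)
        if a:
            assert list_dissimilarity(a, a) == 0.0


class TestVariabilityMatrix:
    def test_identical_lists_give_zero_matrix(self):
        lists = {RunKey(1, 1, 1): {"a"}, RunKey(1, 1, 2): {"a"}}
        mat = variability_matrix(lists)
        assert mat.values.tolist() == [[0.0, 0.0], [0.0, 0.0]]

    def test_labels_use_run_key_codification(self):
        lists = {RunKey(2, 1, 2): {"a"}, RunKey(1, 1, 1): {"b"}}
        mat = variability_matrix(lists)
        assert mat.labels == ("1_1_1", "2_1_2")

    def test_symmetry_on_random_lists(self):
        rng = np.random.default_rng(0)
        lists = {RunKey(1, 1, i + 1): set(rng.choice(list("abcdefgh"), 4, replace=False))
                 for i in range(5)}
        mat = variability_matrix(lists)
        assert np.allclose(mat.values, mat.values.T)


class TestCluster:
    def test_closest_pair_merges_first(self):
        from nsafpipe import VariabilityMatrix
        m = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = cluster(VariabilityMatrix(("A", "B", "C"), m))
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.1)

    def test_equal_distances_give_equal_heights(self):
        from nsafpipe import VariabilityMatrix
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        tree = cluster(VariabilityMatrix(tuple("ABCD"), m))
        assert np.allclose(tree.merge_heights(), 0.5)

    def test_leaves_are_labels_exactly_once(self):
        rng = np.random.default_rng(1)
        n = 7
        m = rng.random((n, n)) * 0.5
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        from nsafpipe import VariabilityMatrix
        labels = tuple(f"L{i}" for i in range(n))
        tree = cluster(VariabilityMatrix(labels, m))
        assert sorted(tree.leaf_order()) == sorted(labels)

    def test_newick_export_contains_all_labels(self):
        from nsafpipe import VariabilityMatrix
        m = np.array([[0.0, 0.2], [0.2, 0.0]])
        tree = cluster(VariabilityMatrix(("X", "Y"), m))
        nwk = tree.to_newick()
        assert "X" in nwk and "Y" in nwk and nwk.endswith(";")


class TestEntanglement:
    def test_identical_orders_give_zero(self):
        assert entanglement(list("abcd"), list("abcd")).value == 0.0

    def test_exact_reversal_gives_one(self):
        assert entanglement(list("abcde"), list("edcba")).value == 1.0

    def test_adjacent_swap_linear_exponent(self):
        assert entanglement(list("abcd"), list("bacd"), L=1).value == pytest.approx(0.25)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            entanglement(list("abc"), list("abd"))

    def test_random_tree_pairs_stay_in_unit_interval(self):
        from nsafpipe import VariabilityMatrix
        rng = np.random.default_rng(2)
        labels = tuple(f"L{i}" for i in range(8))
        for _ in range(25):
            trees = []
            for _ in range(2):
                m = rng.random((8, 8)) * 0.9
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0.0)
                trees.append(cluster(VariabilityMatrix(labels, m)))
            e = entanglement(*trees)
            assert 0.0 <= e.value <= 1.0
            assert entanglement(trees[0], trees[0]).value == 0.0

    def test_untangling_is_a_rotation_and_self_alignment_is_perfect(self):
        from nsafpipe import VariabilityMatrix
        rng = np.random.default_rng(3)
        labels = tuple(f"L{i}" for i in range(10))
        for _ in range(10):
            m = rng.random((10, 10))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = cluster(VariabilityMatrix(labels, np.clip(m, 0, 1)))
            # rotating toward the tree's own leaf order changes nothing
            assert untangle_leaf_order(tree, tree.leaf_order()) == tree.leaf_order()
            assert entanglement(tree.leaf_order(), tree, untangle=True).value == 0.0
            # rotations permute leaves without touching the label set
            unt = untangle_leaf_order(tree, list(labels))
            assert sorted(unt) == sorted(labels)
            assert 0.0 <= entanglement(list(labels), tree, untangle=True).value <= 1.0

    def test_untangling_recovers_dataset_structure(self, default_study):
        """On a study whose runs cluster cleanly by dataset, rotating the
        clustering toward the design order yields near-perfect alignment."""
        from nsafpipe import LadderRules, run_ladder
        study, _ = default_study
        ladder = run_ladder(study, LadderRules.chorionic_villus_rules())
        mat = variability_matrix(stage_run_lists(study, ladder, "I_successful"))
        tree = cluster(mat)
        e = entanglement(design_leaf_order(study), tree, untangle=True)
        assert e.value <= 0.25


class TestRankSum:
    def test_fully_separated_groups(self):
        res = rank_sum_exact([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        res = rank_sum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_symmetry_under_group_swap(self):
        a, b = [0.1, 0.5, 0.4], [0.2, 0.9, 0.3, 0.7]
        assert rank_sum_exact(a, b).p_value == pytest.approx(rank_sum_exact(b, a).p_value)

    def test_critical_value_at_six_vs_six(self):
        assert exact_critical_value(6, 6, alpha=0.05) == 5

    def test_matches_enumeration_oracle_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for n1 in (1, 2, 3, 4):
            for n2 in (1, 2, 3, 4):
                a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1].tolist()
                b = [x for x in np.arange(1.0, n1 + n2 + 1) if x not in a]
                res = rank_sum_exact(a, b)
                w, p = oracle_ranksum(a, b)
                assert res.statistic == pytest.approx(w)
                assert res.p_value == pytest.approx(p)

    def test_large_groups_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(20).tolist(), rng.random(25).tolist()
        res = rank_sum_exact(a, b)
        assert res.method == "normal"
        assert 0 < res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_exact([], [1.0])


class TestProtocolComparison:
    def test_group_structure_and_symmetry(self, default_study):
        study, _ = default_study
        ladder = run_ladder(study, LadderRules.chorionic_villus_rules())
        res = protocol_variability_comparison(study, ladder, "Q_reliably", (2, 5), (3, 6))
        # two 3-replicate datasets per group -> C(3,2) * 2 = 6 values each
        assert (res.n1, res.n2) == (6, 6)
        assert res.method == "exact"
        swapped = protocol_variability_comparison(study, ladder, "Q_reliably", (3, 6), (2, 5))
        assert res.p_value == pytest.approx(swapped.p_value)

    def test_identical_groups_are_indistinguishable(self, default_study):
        study, _ = default_study
        ladder = run_ladder(study, LadderRules.chorionic_villus_rules())
        res = protocol_variability_comparison(study, ladder, "I_successful", (2,), (2,))
        assert res.p_value == 1.0

    def test_design_reference_order_matches_sorted_runs(self, default_study):
        study, _ = default_study
        order = design_leaf_order(study)
        assert order[0] == "1_1_1" and len(order) == len(study.runs)
        lists = stage_run_lists(study, run_ladder(study, LadderRules.chorionic_villus_rules()),
                                "I_successful")
        assert set(map(str, lists)) == set(order)
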