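"""Loss functions, reduced trees, ranking curves, AUC, contingency table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from superboot import (
    TreeError,
    all_or_nothing,
    auc,
    bipartitions,
    clade_supports,
    parse_newick,
    random_tree,
    ranking_curve,
    reduce_tree,
    rf_decompose,
    support_comparison,
    tp_at_fp,
    write_newick,
)

REF = "((A,B),C,(D,E));"
NNI = "((A,C),B,(D,E));"


class TestAllOrNothing:
    def test_branch_lengths_do_not_matter(self):
        a = parse_newick("((A:1,B:2),C:3,(D:1,E:1));")
        b = parse_newick("((A:9,B:9),C:9,(D:9,E:9));")
        assert all_or_nothing(a, b) == 0

    def test_one_nni_neighbor_is_a_loss(self):
        assert all_or_nothing(parse_newick(REF), parse_newick(NNI)) == 1

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(TreeError):
            all_or_nothing(parse_newick(REF), parse_newick("((A,B),C,(D,X));"))

    def test_consistent_with_rf(self):
        for est in (REF, NNI):
            d = rf_decompose(parse_newick(est), parse_newick(REF))
            assert (all_or_nothing(parse_newick(est), parse_newick(REF)) == 0) == (
                d.rf == 0
            )


class TestRFDecompose:
    def test_identical_trees(self):
        d = rf_decompose(parse_newick(REF), parse_newick(REF))
        assert (d.e1, d.e2, d.rf) == (0, 0, 0)

    def test_five_leaf_nni_pair(self):
        d = rf_decompose(parse_newick(NNI), parse_newick(REF))
        assert (d.e1, d.e2, d.rf) == (1, 1, 2)

    def test_star_estimate_has_only_type_ii(self):
        star = parse_newick("(A,B,C,D,E,F);")
        truth = random_tree(6, seed=1)
        relabel = dict(zip(sorted(l.taxon.label for l in truth.leaf_node_iter()),
                           "ABCDEF"))
        for leaf in truth.leaf_node_iter():
            leaf.taxon.label = relabel[leaf.taxon.label]
        d = rf_decompose(star, truth)
        assert (d.e1, d.e2, d.rf) == (0, 3, 3)

    def test_symmetry_swaps_e1_e2(self):
        for seed in range(5):
            a = random_tree(8, seed=seed)
            b = random_tree(8, seed=seed + 100)
            ab = rf_decompose(a, b)
            ba = rf_decompose(b, a)
            assert (ab.e1, ab.e2) == (ba.e2, ba.e1)


class TestReduceTree:
    def _supports(self, tree, values):
        splits = sorted(bipartitions(tree), key=sorted)
        return dict(zip(splits, values))

    def test_full_support_keeps_tree(self):
        t = random_tree(6, seed=3)
        sup = self._supports(t, [1.0] * 3)
        red = reduce_tree(t, sup, 100)
        assert bipartitions(red.tree) == bipartitions(t)

    def test_threshold_zero_keeps_tree(self):
        t = random_tree(6, seed=3)
        sup = self._supports(t, [0.0, 0.2, 0.9])
        assert bipartitions(reduce_tree(t, sup, 0).tree) == bipartitions(t)

    def test_one_weak_edge_collapses_into_polytomy(self):
        t = parse_newick("(((A,B),(C,D)),E,F);")
        splits = bipartitions(t)
        weak = frozenset("CD")
        sup = {s: (0.49 if s == weak else 0.99) for s in splits}
        red = reduce_tree(t, sup, 50)
        assert bipartitions(red.tree) == splits - {weak}

    def test_support_exactly_at_threshold_survives(self):
        t = random_tree(6, seed=4)
        sup = self._supports(t, [0.5] * 3)
        assert bipartitions(reduce_tree(t, sup, 50).tree) == bipartitions(t)

    def test_missing_supports_rejected(self):
        t = random_tree(6, seed=5)
        with pytest.raises(TreeError, match="missing"):
            reduce_tree(t, {}, 50)

    def test_leafset_preserved_and_labels_written(self):
        t = random_tree(7, seed=6)
        sup = self._supports(t, [0.3, 0.6, 0.8, 1.0])
        red = reduce_tree(t, sup, 50)
        assert sorted(l.taxon.label for l in red.tree.leaf_node_iter()) == sorted(
            l.taxon.label for l in t.leaf_node_iter()
        )
        assert "60" in write_newick(red.tree)

    def test_raising_threshold_trades_type_i_for_type_ii(self):
        """e1 never increases and e2 never decreases from S=50 to S=95."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            truth = random_tree(8, seed=seed)
            est = random_tree(8, seed=seed + 50)
            sup = {s: float(rng.uniform(0, 1)) for s in bipartitions(est)}
            d50 = rf_decompose(reduce_tree(est, sup, 50).tree, truth)
            d95 = rf_decompose(reduce_tree(est, sup, 95).tree, truth)
            assert d95.e1 <= d50.e1
            assert d95.e2 >= d50.e2


class TestRankingCurve:
    def test_hand_walked_sweep(self):
        curve = ranking_curve([9, 8, 7, 6, 5], [1, 1, 0, 1, 0])
        assert curve.points == ((0, 1), (0, 2), (1, 2), (1, 3), (2, 3))
        assert tp_at_fp(curve, 1) == 3

    def test_perfect_separation(self):
        curve = ranking_curve([5, 4, 3, 2], [1, 1, 0, 0])
        assert tp_at_fp(curve, 0) == 2

    def test_tie_block_all_or_nothing(self):
        curve = ranking_curve([1, 1, 1, 1], [1, 1, 0, 0])
        assert curve.points == ((2, 2),)
        assert tp_at_fp(curve, 1) == 0
        assert tp_at_fp(curve, 2) == 2

    def test_monotone_in_budget_and_endpoint(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        if not labels.any() or labels.all():
            labels[0], labels[1] = True, False
        curve = ranking_curve(scores, labels)
        n_neg = int((~labels).sum())
        prev = -1
        for budget in range(n_neg + 1):
            tp = tp_at_fp(curve, budget)
            assert tp >= prev
            prev = tp
        assert tp_at_fp(curve, n_neg) == int(labels.sum())
        assert curve.points[-1] == (n_neg, int(labels.sum()))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ranking_curve([1, 2], [1, 1])


class TestAUC:
    def test_perfect_and_hand_example(self):
        assert auc([5, 4, 1, 0], [1, 1, 0, 0]) == 1.0
        # positives score 3 and 1, negative scores 2: one win, one loss
        assert auc([3, 2, 1], [1, 0, 1]) == 0.5

    def test_complement_property(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        assert auc(scores, labels) + auc(scores, ~labels) == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    def test_matches_pair_enumeration_oracle(self, seed):
        """Mann-Whitney definition: P(pos > neg) + 0.5 P(tie)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        scores = rng.integers(0, 5, size=n).astype(float)  # forces ties
        labels = rng.random(n) < 0.5
        if not labels.any() or labels.all():
            labels[0] = ~labels[0]
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))


class TestSupportComparison:
    def test_strata_counts_and_percentages(self):
        records = (
            [(70, 50, True)] * 3
            + [(70, 50, False)] * 1
            + [(40, 50, True)] * 1
            + [(40, 50, False)] * 3
            + [(50, 50, True)] * 2
        )
        table = support_comparison(records)
        assert table.counts[(">", True)] == 3
        assert table.counts[("<", False)] == 3
        assert table.counts[("=", True)] == 2
        assert table.percent_correct(">") == pytest.approx(75.0)
        assert table.percent_correct("<") == pytest.approx(25.0)
        assert table.n_records == 10

    def test_empty_stratum_reports_missing(self):
        table = support_comparison([(70, 50, True)])
        assert table.percent_correct("<") is None

    def test_cutoff_restriction(self):
        records = [(80, 70, True), (50, 40, False), (80, 30, True)]
        above = support_comparison(records, cutoff=60, side="above")
        below = support_comparison(records, cutoff=60, side="below")
        assert above.n_records == 1 and above.overall_percent_correct == 100.0
        assert below.n_records == 1 and below.overall_percent_correct == 0.0

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValueError):
            support_comparison([(101, 50, True)])
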