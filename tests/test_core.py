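import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gssa.annotation import AnnotationMap
from gssa.core import (
    adjust_fdr,
    apply_fdr,
    classify_terms,
    compare_psg_counts,
    fisher_two_tailed,
    make_partitions,
    run_gssa,
    segmentation_test,
)
from gssa.errors import ValidationError

from .conftest import (
    exact_fisher_two_sided,
    make_ranked,
    map_from_positions,
    naive_bh,
    random_map,
)


class TestMakePartitions:
    def test_n31_p30_gives_unit_cuts(self):
        cuts = [p.position for p in make_partitions(31, 30)]
        assert cuts == list(range(1, 31))

    def test_n62_p30_gives_even_cuts(self):
        cuts = [p.position for p in make_partitions(62, 30)]
        assert cuts == list(range(2, 61, 2))

    def test_n300_p30_first_and_last(self):
        cuts = [p.position for p in make_partitions(300, 30)]
        assert len(cuts) == 30
        assert cuts[0] == 9 and cuts[-1] == 290
        assert all(b > a for a, b in zip(cuts, cuts[1:]))

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValidationError, match="fewer partitions"):
            make_partitions(30, 30)

    def test_duplicate_cuts_collapsed_keeping_first_index(self):
        parts = make_partitions(32, 30)
        positions = [p.position for p in parts]
        assert positions == sorted(set(positions))
        # first occurrence keeps the smallest partition index for that cut
        by_pos = {}
        for k in range(1, 31):
            pos = min(max((k * 32) // 31, 1), 31)
            by_pos.setdefault(pos, k)
        assert [(p.index, p.position) for p in parts] == sorted(
            (v, k) for k, v in by_pos.items()
        )

    @given(st.integers(min_value=31, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_cuts_within_bounds_and_increasing(self, n):
        parts = make_partitions(n, 30)
        positions = [p.position for p in parts]
        assert all(1 <= c <= n - 1 for c in positions)
        assert positions == sorted(set(positions))


class TestFisherTwoTailed:
    def test_perfect_independence(self):
        odds, p = fisher_two_tailed(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_diagonal_table(self):
        odds, p = fisher_two_tailed(3, 0, 0, 3)
        assert odds == math.inf
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_margin(self):
        odds, p = fisher_two_tailed(0, 0, 0, 10)
        assert p == 1.0 and odds == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_two_tailed(-1, 2, 3, 4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_two_tailed(0, 0, 0, 0)

    def test_odds_ratio_conventions(self):
        assert fisher_two_tailed(2, 0, 0, 2)[0] == math.inf
        assert fisher_two_tailed(0, 2, 2, 0)[0] == 0.0
        assert fisher_two_tailed(0, 5, 0, 5)[0] == 1.0  # 0/0 -> 1

    @given(*(st.integers(min_value=0, max_value=15) for _ in range(4)))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p = fisher_two_tailed(a, b, c, d)
        assert p == pytest.approx(exact_fisher_two_sided(a, b, c, d), abs=1e-12)

    @given(*(st.integers(min_value=0, max_value=12) for _ in range(4)))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_transposition(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_two_tailed(a, b, c, d)[1] == pytest.approx(
            fisher_two_tailed(a, c, b, d)[1], abs=1e-12
        )


class TestSegmentationTest:
    def test_term_equal_to_universe_gives_p_one(self):
        ranked = make_ranked(100)
        amap = map_from_positions(ranked, {"all": range(100)})
        results = segmentation_test(ranked, amap)
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_top_block_term_counts_and_minimum(self):
        ranked = make_ranked(300)
        amap = map_from_positions(ranked, {"top": range(15)})
        results = segmentation_test(ranked, amap)
        by_cut = {r.cut_index: r for r in results}
        assert by_cut[9].a == 9  # first cut of N=300
        # every table must match the independent exact oracle
        for r in results:
            assert r.p_value == pytest.approx(
                exact_fisher_two_sided(r.a, r.b, r.c, r.d), abs=1e-12
            )
        # the minimum sits at the smallest cut that contains the block
        best = min(results, key=lambda r: r.p_value)
        candidates = [c for c in by_cut if c >= 15]
        assert best.cut_index == min(candidates)

    def test_count_is_terms_times_partitions(self):
        ranked = make_ranked(1000)
        amap = random_map(ranked, sizes=[20] * 50, seed=3)
        results = segmentation_test(ranked, amap)
        assert len(results) == 50 * 30

    def test_margins_satisfy_invariants(self):
        ranked = make_ranked(500)
        amap = random_map(ranked, sizes=[15, 60, 200], seed=5)
        for r in segmentation_test(ranked, amap):
            assert r.a + r.b == r.cut_index
            assert r.c + r.d == 500 - r.cut_index
            assert r.a + r.c == len(amap.assignments[r.term_id])
            assert 0.0 <= r.p_value <= 1.0

    def test_empty_map_is_error(self):
        ranked = make_ranked(100)
        amap = AnnotationMap.from_sets({}, universe=ranked.gene_ids)
        with pytest.raises(ValidationError):
            segmentation_test(ranked, amap)


class TestAdjustFdr:
    def test_single_p(self):
        np.testing.assert_allclose(adjust_fdr([0.05]), [0.05])

    def test_hand_computed_family_of_four(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_family(self):
        np.testing.assert_allclose(adjust_fdr([0.5] * 7), [0.5] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_fdr([0.1, 1.5])
        with pytest.raises(ValidationError):
            adjust_fdr([-0.1])

    def test_order_preserving(self):
        p = np.random.default_rng(0).uniform(size=200)
        q = adjust_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_quadratic(self, p_values):
        np.testing.assert_allclose(adjust_fdr(p_values), naive_bh(p_values), atol=1e-12)


def _run(ranked, sizes_or_positions, seed=0):
    if isinstance(sizes_or_positions, dict):
        amap = map_from_positions(ranked, sizes_or_positions)
    else:
        amap = random_map(ranked, sizes_or_positions, seed=seed)
    return run_gssa(ranked, amap) + (amap,)


class TestClassifyTerms:
    def test_top_block_is_sh_strict_tier(self):
        ranked = make_ranked(2000)
        _, calls, _, _ = _run(ranked, {"block": range(20), "bg": range(0, 2000, 40)})
        call = {c.term_id: c for c in calls}["block"]
        assert call.verdict == "SH"
        assert call.tier == "FDR_0.1pct"
        assert call.pct_contributing >= 95

    def test_uniformly_scattered_term_is_ns(self):
        ranked = make_ranked(2000)
        _, calls, _, _ = _run(ranked, {"scatter": range(0, 2000, 10)})
        assert calls[0].verdict == "NS"
        assert calls[0].tier == "none"
        assert calls[0].first_significant_partition is None
        assert calls[0].pct_contributing is None

    def test_bottom_block_is_sl(self):
        ranked = make_ranked(2000)
        _, calls, _, _ = _run(ranked, {"tail": range(1980, 2000), "bg": range(0, 2000, 40)})
        call = {c.term_id: c for c in calls}["tail"]
        assert call.verdict == "SL"

    def test_reversal_swaps_verdicts_and_preserves_q(self):
        # N divisible by (P+1) so the cut set is mirror-symmetric
        ranked = make_ranked(3100)
        amap = random_map(ranked, sizes=[15, 40, 40, 100, 300], seed=11)
        amap.assignments = dict(amap.assignments)
        amap.assignments["planted"] = frozenset(ranked.gene_ids[:40])
        _, calls_fwd, _ = run_gssa(ranked, amap)
        _, calls_rev, _ = run_gssa(ranked.reversed(), amap)
        swap = {"SH": "SL", "SL": "SH", "NS": "NS"}
        fwd = {c.term_id: c for c in calls_fwd}
        rev = {c.term_id: c for c in calls_rev}
        assert fwd["planted"].verdict == "SH"
        for term in fwd:
            assert rev[term].verdict == swap[fwd[term].verdict]
            assert rev[term].q_min == pytest.approx(fwd[term].q_min, rel=1e-9)

    def test_label_invariance(self):
        ranked = make_ranked(600)
        amap = random_map(ranked, sizes=[20, 50, 120], seed=2)
        _, calls_a, _ = run_gssa(ranked, amap)

        # consistent relabeling of every gene id in ranking and annotation
        relabel = {g: f"x_{g}" for g in ranked.gene_ids}
        ranked_b = type(ranked)(
            variable=ranked.variable,
            gene_ids=tuple(relabel[g] for g in ranked.gene_ids),
            values=ranked.values,
        )
        amap_b = AnnotationMap.from_sets(
            {t: {relabel[g] for g in gs} for t, gs in amap.assignments.items()},
            universe=[relabel[g] for g in amap.universe],
        )
        _, calls_b, _ = run_gssa(ranked_b, amap_b)
        for ca, cb in zip(calls_a, calls_b):
            assert ca.verdict == cb.verdict
            assert ca.q_min == pytest.approx(cb.q_min)
            assert ca.best_partition.partition_index == cb.best_partition.partition_index

    def test_null_membership_rarely_significant(self):
        ranked = make_ranked(2000, seed=9)
        amap = random_map(ranked, sizes=[30] * 40, seed=9)
        _, calls, _ = run_gssa(ranked, amap)
        frac = sum(c.verdict != "NS" for c in calls) / len(calls)
        assert frac <= 0.05

    def test_unset_q_raises(self):
        ranked = make_ranked(200)
        amap = random_map(ranked, sizes=[20], seed=0)
        results = segmentation_test(ranked, amap)
        with pytest.raises(ValidationError, match="q-values"):
            classify_terms(results)

    def test_family_size_reported(self):
        ranked = make_ranked(500)
        amap = random_map(ranked, sizes=[20, 30], seed=1)
        results = segmentation_test(ranked, amap)
        assert apply_fdr(results) == 2 * 30


class TestComparePsgCounts:
    def _calls_and_map(self, sh_counts, sl_counts):
        # build modules of 20 genes with the requested number flagged
        assignments, flags, calls = {}, {}, []
        gid = 0
        from gssa.core import PartitionResult, TermCall

        def add(verdict, counts):
            nonlocal gid
            for i, n_psg in enumerate(counts):
                term = f"{verdict}{i}"
                genes = []
                for j in range(20):
                    g = f"g{gid}"
                    gid += 1
                    flags[g] = 1 if j < n_psg else 0
                    genes.append(g)
                assignments[term] = set(genes)
                pr = PartitionResult(term, 1, 10, 5, 5, 15, 15, 1.0, 0.5, 0.5)
                calls.append(TermCall(term, verdict, "FDR_5pct", 0.01, pr, pr, 50.0, 20))

        add("SH", sh_counts)
        add("SL", sl_counts)
        amap = AnnotationMap.from_sets(assignments)
        return calls, amap, flags

    def test_identical_groups(self):
        calls, amap, flags = self._calls_and_map([5, 5, 5], [5, 5, 5])
        cmp = compare_psg_counts(calls, amap, flags)
        assert cmp.computable
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_clear_separation(self):
        calls, amap, flags = self._calls_and_map([10, 12, 11, 9], [1, 0, 2, 1])
        cmp = compare_psg_counts(calls, amap, flags)
        assert cmp.computable
        assert cmp.mean_sh == pytest.approx(10.5)
        assert cmp.mean_sl == pytest.approx(1.0)
        assert cmp.t_statistic > 0
        assert cmp.p_value < 0.01

    def test_single_module_group_not_computable(self):
        calls, amap, flags = self._calls_and_map([5, 6], [4])
        cmp = compare_psg_counts(calls, amap, flags)
        assert not cmp.computable
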