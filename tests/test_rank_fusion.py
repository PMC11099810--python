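"""RRF, weighted linear combination, ensemble and depth-restricted reranking."""

import numpy as np
import pytest

from qualrank import (
    Document,
    Ranking,
    Topic,
    depth_restricted_rerank,
    ensemble_rerank,
    rrf,
    weight_sweep,
    weighted_combine,
)
from tests.conftest import make_ranking


class TestRrf:
    def test_single_input_is_identity_ordering(self):
        r = make_ranking("t", ["a", "b", "c"])
        assert rrf([r]).doc_ids == ["a", "b", "c"]

    def test_hand_computed_two_list_example(self):
        fused = rrf([make_ranking("t", ["a", "b"]), make_ranking("t", ["b", "c"])], rrf_k=60)
        assert fused.doc_ids == ["b", "a", "c"]
        scores = dict(fused.entries)
        assert scores["b"] == pytest.approx(1 / 62 + 1 / 61)
        assert scores["a"] == pytest.approx(1 / 61)
        assert scores["c"] == pytest.approx(1 / 62)

    def test_tie_broken_by_doc_id(self):
        fused = rrf([make_ranking("t", ["a", "b", "c"]), make_ranking("t", ["b", "a", "c"])])
        assert fused.doc_ids == ["a", "b", "c"]

    def test_invariant_under_input_permutation(self):
        lists = [
            make_ranking("t", ["a", "b", "d"]),
            make_ranking("t", ["c", "a"]),
            make_ranking("t", ["d", "b", "a", "c"]),
        ]
        assert rrf(lists).entries == rrf(lists[::-1]).entries

    def test_mixed_topics_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            rrf([make_ranking("t1", ["a"]), make_ranking("t2", ["a"])])


class _FixedScorer:
    """Scorer backed by a doc_id -> score table."""

    def __init__(self, name, table):
        self.name = name
        self.table = table

    def score(self, topic, doc):
        return self.table[doc.doc_id]


def _docs(ids):
    return {d: Document(d, f"text of {d}") for d in ids}


class TestEnsembleRerank:
    topic = Topic("t", "q")

    def test_single_oracle_scorer_sorts_by_score(self):
        base = make_ranking("t", ["a", "b", "c"])
        scorer = _FixedScorer("oracle", {"a": 0.1, "b": 0.9, "c": 0.5})
        out = ensemble_rerank(base, [scorer], self.topic, _docs("abc"))
        assert out.doc_ids == ["b", "c", "a"]

    def test_identical_scorers_idempotent(self):
        base = make_ranking("t", ["a", "b", "c"])
        s = _FixedScorer("s", {"a": 3, "b": 1, "c": 2})
        one = ensemble_rerank(base, [s], self.topic, _docs("abc"))
        two = ensemble_rerank(base, [s, s], self.topic, _docs("abc"))
        assert one.doc_ids == two.doc_ids

    def test_three_scorers_equal_brute_force_rrf(self):
        ids = ["a", "b", "c", "d", "e"]
        base = make_ranking("t", ids)
        rng = np.random.default_rng(3)
        scorers = [
            _FixedScorer(f"s{i}", {d: float(rng.random()) for d in ids}) for i in range(3)
        ]
        out = ensemble_rerank(base, scorers, self.topic, _docs(ids), rrf_k=60)
        # brute force: sort each table, sum reciprocal ranks
        fused = {}
        for s in scorers:
            order = sorted(ids, key=lambda d: (-s.table[d], d))
            for rank, d in enumerate(order, start=1):
                fused[d] = fused.get(d, 0.0) + 1 / (60 + rank)
        expected = sorted(ids, key=lambda d: (-fused[d], d))
        assert out.doc_ids == expected

    def test_scorer_failure_names_scorer_and_doc(self):
        base = make_ranking("t", ["a", "b"])
        broken = _FixedScorer("broken", {"a": 1.0})  # no entry for b
        with pytest.raises(RuntimeError, match="broken.*doc b"):
            ensemble_rerank(base, [broken], self.topic, _docs("ab"))

    def test_covers_exactly_base_doc_set(self):
        base = make_ranking("t", ["a", "b", "c"])
        s = _FixedScorer("s", {"a": 1, "b": 2, "c": 3, "zz": 9})
        out = ensemble_rerank(base, [s], self.topic, _docs(["a", "b", "c", "zz"]))
        assert sorted(out.doc_ids) == ["a", "b", "c"]


class TestWeightedCombine:
    def test_mask_weight_selects_single_ranking(self):
        r1 = make_ranking("t", ["a", "b", "c"])
        r2 = make_ranking("t", ["c", "b", "a"])
        out = weighted_combine([r1, r2], [1.0, 0.0])
        assert out.doc_ids == ["a", "b", "c"]

    def test_zero_weight_equals_dropping_the_model(self):
        r1 = make_ranking("t", ["a", "b", "c"])
        r2 = make_ranking("t", ["b", "c", "a"])
        r3 = make_ranking("t", ["c", "a", "b"])
        with_zero = weighted_combine([r1, r2, r3], [0.0, 0.33, 0.33])
        without = weighted_combine([r2, r3], [0.33, 0.33])
        assert with_zero.doc_ids == without.doc_ids

    def test_hand_computed_normalized_sum(self):
        r1 = Ranking("t", [("a", 4.0), ("b", 2.0), ("c", 0.0)])
        r2 = Ranking("t", [("b", 10.0), ("a", 5.0)])
        out = weighted_combine([r1, r2], [1.0, 1.0])
        scores = dict(out.entries)
        # minmax: r1 -> a=1, b=0.5, c=0; r2 -> b=1, a=0; c missing from r2
        assert scores["a"] == pytest.approx(1.0)
        assert scores["b"] == pytest.approx(1.5)
        assert scores["c"] == pytest.approx(0.0)

    def test_scale_invariance_of_ordering(self):
        rng = np.random.default_rng(0)
        lists = [
            Ranking.from_scores("t", {f"d{i}": float(rng.random()) for i in range(8)})
            for _ in range(3)
        ]
        w = [0.2, 0.5, 0.3]
        a = weighted_combine(lists, w)
        b = weighted_combine(lists, [x * 7.5 for x in w])
        assert a.doc_ids == b.doc_ids

    def test_constant_score_list_normalizes_to_one(self):
        r1 = Ranking("t", [("a", 2.0), ("b", 2.0)])
        out = weighted_combine([r1], [1.0])
        assert dict(out.entries) == {"a": 1.0, "b": 1.0}

    def test_all_zero_weights_rejected(self):
        r = make_ranking("t", ["a"])
        with pytest.raises(ValueError):
            weighted_combine([r, r], [0.0, 0.0])


class TestWeightSweep:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.lists = [
            Ranking.from_scores("t", {f"d{i}": float(rng.random()) for i in range(6)})
            for _ in range(4)
        ]
        self.eval_fn = lambda r: float(r.doc_ids.index("d0"))  # arbitrary metric

    def test_grid_zero_reproduces_remaining_combination(self):
        curve = weight_sweep(self.lists, 0, [0.0], self.eval_fn, fixed_weight=0.33)
        dropped = weighted_combine(self.lists[1:], [0.33] * 3)
        assert curve[0][1] == self.eval_fn(dropped)

    def test_deterministic_given_inputs(self):
        grid = [0.0, 0.5, 1.0, 2.0]
        a = weight_sweep(self.lists, 2, grid, self.eval_fn)
        b = weight_sweep(self.lists, 2, grid, self.eval_fn)
        assert a == b

    def test_vary_index_out_of_range(self):
        with pytest.raises(ValueError):
            weight_sweep(self.lists, 9, [0.5], self.eval_fn)


class TestDepthRestrictedRerank:
    @staticmethod
    def reverse_reranker(prefix: Ranking) -> Ranking:
        ids = prefix.doc_ids[::-1]
        return Ranking(prefix.topic_id, [(d, float(len(ids) - i)) for i, d in enumerate(ids)])

    def test_depth_zero_is_identity(self):
        base = make_ranking("t", ["a", "b", "c"])
        assert depth_restricted_rerank(base, [self.reverse_reranker], 0).doc_ids == ["a", "b", "c"]

    def test_depth_beyond_length_equals_full_rerank(self):
        base = make_ranking("t", ["a", "b", "c"])
        d3 = depth_restricted_rerank(base, [self.reverse_reranker], 3)
        d99 = depth_restricted_rerank(base, [self.reverse_reranker], 99)
        assert d3.doc_ids == d99.doc_ids

    def test_depth_three_manual_construction(self):
        base = make_ranking("t", ["a", "b", "c", "d", "e"])
        out = depth_restricted_rerank(base, [self.reverse_reranker], 3, rrf_k=60)
        # manual: fuse prefix [a,b,c] with reversed [c,b,a]; suffix [d,e] appended
        fused = {}
        for lst in (["a", "b", "c"], ["c", "b", "a"]):
            for rank, d in enumerate(lst, start=1):
                fused[d] = fused.get(d, 0.0) + 1 / (60 + rank)
        expected = sorted(fused, key=lambda d: (-fused[d], d)) + ["d", "e"]
        assert out.doc_ids == expected

    def test_top_set_membership_preserved(self):
        base = make_ranking("t", [f"d{i}" for i in range(10)])
        for depth in (2, 5, 7):
            out = depth_restricted_rerank(base, [self.reverse_reranker], depth)
            assert set(out.doc_ids[:depth]) == set(base.doc_ids[:depth])
            assert out.doc_ids[depth:] == base.doc_ids[depth:]
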