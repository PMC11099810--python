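"""Truncated RBO compatibility, ideal rankings, help/harm reporting, nDCG."""

import itertools
import math

import pytest

from qualrank import (
    CompatibilityParams,
    Judgment,
    JudgmentSet,
    Ranking,
    Topic,
    compatibility,
    derive_preference_labels,
    help_harm_report,
    ideal_ranking,
    interpret_depth10,
    ndcg,
    truncated_rbo,
)
from tests.conftest import make_ranking


def rbo_oracle(r_docs, i_docs, p, K):
    """Brute-force term-by-term summation with explicit prefix intersections."""
    total = 0.0
    for d in range(1, K + 1):
        overlap = len(set(r_docs[:d]) & set(i_docs[:d]))
        total += (1 - p) * p ** (d - 1) * overlap / d
    return total


class TestTruncatedRbo:
    def test_worked_three_doc_example(self):
        R = make_ranking("t", ["d1", "d2", "d3"])
        I = make_ranking("t", ["d2", "d1"])
        assert truncated_rbo(R, I, p=0.5, K=3) == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_ideal_is_zero(self):
        R = make_ranking("t", ["d1", "d2"])
        assert truncated_rbo(R, make_ranking("t", []), p=0.5, K=3) == 0.0

    def test_identity_equals_one_minus_p_to_K(self):
        R = make_ranking("t", [f"d{i}" for i in range(12)])
        for p, K in [(0.5, 3), (0.95, 10)]:
            assert truncated_rbo(R, R, p=p, K=K) == pytest.approx(1 - p**K, abs=1e-12)

    def test_parameter_validation(self):
        R = make_ranking("t", ["d1"])
        with pytest.raises(ValueError):
            truncated_rbo(R, R, p=1.5, K=3)
        with pytest.raises(ValueError):
            truncated_rbo(R, R, p=0.5, K=0)

    def test_matches_oracle_on_partial_overlap(self):
        R = make_ranking("t", ["a", "b", "c", "d", "e"])
        I = make_ranking("t", ["c", "a", "f"])
        for p in (0.5, 0.9):
            for K in (1, 2, 4, 8):
                assert truncated_rbo(R, I, p=p, K=K) == pytest.approx(
                    rbo_oracle(R.doc_ids, I.doc_ids, p, K), abs=1e-12
                )


class TestCompatibility:
    def test_self_compatibility_is_one(self):
        R = make_ranking("t", ["d1", "d2", "d3"])
        assert compatibility(R, R, p=0.5, K=3) == pytest.approx(1.0)

    def test_worked_example_is_0_4(self):
        R = make_ranking("t", ["d1", "d2", "d3"])
        I = make_ranking("t", ["d2", "d1"])
        assert compatibility(R, I, p=0.5, K=3) == pytest.approx(0.4, abs=1e-12)

    def test_disjoint_is_zero_and_empty_ideal_is_zero(self):
        R = make_ranking("t", ["d1", "d2"])
        assert compatibility(R, make_ranking("t", ["x", "y"]), p=0.5, K=3) == 0.0
        assert compatibility(R, make_ranking("t", []), p=0.5, K=3) == 0.0

    def test_large_K_identity_approaches_one_for_any_p(self):
        R = make_ranking("t", [f"d{i}" for i in range(5)])
        for p in (0.5, 0.95, 0.99):
            assert compatibility(R, R, p=p, K=5000) == pytest.approx(1.0)

    def test_promoting_an_ideal_doc_past_junk_never_decreases_compatibility(self):
        """Swapping a document of I above an adjacent non-ideal document cannot
        hurt (promoting it past another ideal document can, by breaking their
        ideal relative order, so that case is excluded)."""
        docs = ["a", "b", "c", "d"]
        I = make_ranking("t", ["c", "a"])
        ideal_docs = set(I.doc_ids)
        for perm in itertools.permutations(docs):
            base = compatibility(make_ranking("t", list(perm)), I, p=0.95, K=4)
            for target in ("a", "c"):
                pos = perm.index(target)
                if pos == 0 or perm[pos - 1] in ideal_docs:
                    continue
                promoted = list(perm)
                promoted.insert(pos - 1, promoted.pop(pos))
                better = compatibility(make_ranking("t", promoted), I, p=0.95, K=4)
                assert better >= base - 1e-12


class TestIdealRanking:
    def test_no_harmful_docs_gives_empty_ideal(self, toy_judgments):
        ideal = ideal_ranking(toy_judgments, "102", "harmful")
        assert ideal.doc_ids == ["dA"]  # 102/dA is the only harmful one
        no_docs = JudgmentSet()
        assert ideal_ranking(no_docs, "101", "harmful").doc_ids == []

    def test_ordering_by_grade_then_credibility_then_doc_id(self):
        topics = [Topic("h", "q", stance="helpful")]
        js = JudgmentSet()
        js.add(Judgment("h", "dLow", usefulness=1, supportiveness="supportive", credibility=1))
        js.add(Judgment("h", "dHigh", usefulness=2, supportiveness="supportive", credibility=0))
        js.add(Judgment("h", "dHighCred", usefulness=2, supportiveness="supportive", credibility=1))
        labeled = derive_preference_labels(js, topics)
        ideal = ideal_ranking(labeled, "h", "helpful")
        assert ideal.doc_ids == ["dHighCred", "dHigh", "dLow"]

    def test_order_invariant_under_input_permutation(self):
        topics = [Topic("h", "q", stance="helpful")]
        rows = [
            Judgment("h", f"d{i}", usefulness=(i * 7) % 3, supportiveness="supportive",
                     credibility=i % 2)
            for i in range(10)
        ]
        a = derive_preference_labels(JudgmentSet(rows), topics)
        b = derive_preference_labels(JudgmentSet(rows[::-1]), topics)
        assert ideal_ranking(a, "h", "helpful").doc_ids == ideal_ranking(b, "h", "helpful").doc_ids

    def test_bad_polarity_rejected(self, toy_judgments):
        with pytest.raises(ValueError):
            ideal_ranking(toy_judgments, "101", "neutral")


class TestHelpHarmReport:
    def test_ideal_run_scores_help_1_harm_0(self, toy_topics, toy_judgments):
        ideal = ideal_ranking(toy_judgments, "101", "helpful")
        report = help_harm_report([ideal], toy_judgments, toy_topics)
        (row,) = report.per_topic
        assert row.help == pytest.approx(1.0)
        assert row.harm == 0.0
        assert row.help_harm == pytest.approx(1.0)

    def test_pure_harm_run_scores_minus_one(self, toy_topics, toy_judgments):
        ideal_harm = ideal_ranking(toy_judgments, "101", "harmful")
        report = help_harm_report([ideal_harm], toy_judgments, toy_topics)
        (row,) = report.per_topic
        assert row.help_harm == pytest.approx(-1.0)

    def test_macro_average_is_recomputable(self, small_benchmark):
        topics, corpus, qrels = small_benchmark
        runs = [ideal_ranking(qrels, t.topic_id, "helpful") for t in topics]
        runs = [r for r in runs if r.entries]
        report = help_harm_report(runs, qrels, topics)
        manual = sum(t.help - t.harm for t in report.per_topic) / len(report.per_topic)
        assert report.mean("help_harm") == pytest.approx(manual)
        # help_harm = help - harm in every aggregate
        for part in ("helpful_T", "unhelpful_T", "all_T"):
            assert report.mean("help_harm", part) == pytest.approx(
                report.mean("help", part) - report.mean("harm", part)
            )

    def test_run_topic_missing_from_qrels_is_error(self, toy_topics, toy_judgments):
        stray = make_ranking("999", ["dA"])
        with pytest.raises(ValueError, match="999"):
            help_harm_report([stray], toy_judgments, toy_topics)

    def test_help_harm_antisymmetric_under_label_swap(self, toy_topics, toy_judgments):
        from dataclasses import replace

        run = make_ranking("101", ["dA", "dC", "dB"])
        fwd = help_harm_report([run], toy_judgments, toy_topics)
        swap = {"helpful": "harmful", "harmful": "helpful", "neither": "neither"}
        swapped = JudgmentSet(
            [replace(j, preference=swap[j.preference]) for j in toy_judgments]
        )
        rev = help_harm_report([run], swapped, toy_topics)
        assert fwd.per_topic[0].help_harm == pytest.approx(-rev.per_topic[0].help_harm)


class TestNdcg:
    def test_ideal_order_scores_one(self, toy_judgments):
        run = ideal_ranking(toy_judgments, "101", "helpful")
        assert ndcg(run, toy_judgments, "helpful") == pytest.approx(1.0)

    def test_single_relevant_at_rank_two(self):
        topics = [Topic("h", "q", stance="helpful")]
        js = JudgmentSet()
        js.add(Judgment("h", "rel", usefulness=1, supportiveness="supportive"))
        labeled = derive_preference_labels(js, topics)
        run = make_ranking("h", ["junk", "rel"])
        expected = (1 / math.log2(3)) / (1 / math.log2(2))
        assert ndcg(run, labeled, "helpful") == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.6309, abs=1e-4)

    def test_no_labeled_docs_scores_zero(self):
        run = make_ranking("t", ["d1"])
        assert ndcg(run, JudgmentSet(), "helpful") == 0.0


class TestDepth10Interpretation:
    def test_empty_intersection_gives_zero_help(self, toy_topics, toy_judgments):
        run = make_ranking("101", ["x1", "x2"])
        d10 = interpret_depth10([run], toy_judgments, toy_topics)
        assert d10.report.per_topic[0].help == 0.0

    def test_only_helpful_top10_and_short_ideal_gives_help_harm_one(self):
        topics = [Topic("h", "q", stance="helpful")]
        js = JudgmentSet()
        for i in range(5):
            js.add(Judgment("h", f"d{i}", usefulness=2, supportiveness="supportive"))
        labeled = derive_preference_labels(js, topics)
        run = ideal_ranking(labeled, "h", "helpful")
        d10 = interpret_depth10([run], labeled, topics)
        assert d10.report.per_topic[0].help_harm == pytest.approx(1.0)
        assert d10.mean_helpful_in_top10 == 5.0

    def test_one_helpful_doc_worth_roughly_ten_points(self):
        """Enumerate the 10 placements of a single ideal document."""
        topics = [Topic("h", "q", stance="helpful")]
        js = JudgmentSet()
        for i in range(12):
            js.add(Judgment("h", f"h{i:02d}", usefulness=1, supportiveness="supportive"))
        labeled = derive_preference_labels(js, topics)
        values = []
        for pos in range(10):
            docs = [f"x{j}" for j in range(10)]
            docs[pos] = "h00"  # the one retrieved helpful document
            run = make_ranking("h", docs)
            d10 = interpret_depth10([run], labeled, topics)
            values.append(d10.report.per_topic[0].help)
        assert values == sorted(values, reverse=True)  # earlier placement, higher help
        # one helpful document moves help compatibility by ~10 points on average
        mean = sum(values) / len(values)
        assert 0.03 < mean < 0.20
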