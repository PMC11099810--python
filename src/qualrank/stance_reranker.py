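"""Supportiveness reranking: claim checking, evidence-majority stance, tiering.

A claim checker labels each (topic, document) pair as supporting, refuting or
neutral toward the topic's treatment claim.  Because web documents cannot be
trusted as ground truth, the topic's stance is *inferred* by majority vote
over the checker's labels for the top-k documents of the base ranking — the
working assumption being that a scientific fact is backed by the largest body
of evidence.  Documents are then reordered in three tiers: those agreeing
with the inferred stance first, neutral documents second, and disagreeing
documents last, each tier preserving the base order.  With several checkers,
the per-checker tiered rankings are fused with reciprocal rank fusion.

If the vote is tied or all labels are neutral the stance is *undecided* and
the base order is returned unchanged — an automatic system must not fabricate
a stance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence, runtime_checkable

from .benchmark_io import Document, Ranking, Topic
from .rank_fusion import DEFAULT_RRF_K, rrf

CLAIM_LABELS = ("supports", "refutes", "neutral")
DEFAULT_VOTE_K = 10


@runtime_checkable
class ScorerContract(Protocol):
    """A reranking model: deterministic real-valued score per (topic, doc);
    higher means stronger on the scorer's quality dimension."""

    name: str

    def score(self, topic: Topic, doc: Document) -> float: ...


@runtime_checkable
class ClaimCheckerContract(Protocol):
    """A claim-checking model: (label, confidence) per (topic, doc), with
    label in {supports, refutes, neutral}."""

    name: str

    def label(self, topic: Topic, doc: Document) -> tuple[str, float]: ...


@dataclass(frozen=True)
class StanceDecision:
    """Outcome of the evidence-majority vote over top-k claim labels."""

    stance: str  # supported | refuted | undecided
    supports_votes: int
    refutes_votes: int
    neutral_votes: int
    k: int


def infer_topic_stance(labels: Sequence[str], k: int = DEFAULT_VOTE_K) -> StanceDecision:
    """Majority vote over the non-neutral labels among the top-k.

    ``labels`` must be ordered by the base ranking.  Ties (including the
    all-neutral case) yield ``undecided``.
    """
    if not labels:
        raise ValueError("empty label list")
    if k < 1:
        raise ValueError("k must be >= 1")
    top = labels[:k]
    for lab in top:
        if lab not in CLAIM_LABELS:
            raise ValueError(f"unknown claim label {lab!r}")
    s = sum(1 for lab in top if lab == "supports")
    r = sum(1 for lab in top if lab == "refutes")
    n = sum(1 for lab in top if lab == "neutral")
    if s > r:
        stance = "supported"
    elif r > s:
        stance = "refuted"
    else:
        stance = "undecided"
    return StanceDecision(stance=stance, supports_votes=s, refutes_votes=r, neutral_votes=n, k=k)


def tier_rerank(
    base: Ranking, labels: Sequence[str], stance_decision: StanceDecision
) -> Ranking:
    """Three-tier stable reorder: correct, neutral, incorrect.

    "Correct" means the label agrees with the inferred stance (supports when
    supported, refutes when refuted).  Each tier preserves base's internal
    order; an undecided stance returns base unchanged.  Output scores are
    re-derived as descending ranks.
    """
    if len(labels) != len(base.entries):
        missing = len(base.entries) - len(labels)
        raise ValueError(f"label missing for {missing} document(s)")
    if stance_decision.stance == "undecided":
        return base
    correct_label = "supports" if stance_decision.stance == "supported" else "refutes"
    tiers: dict[str, list[str]] = {"correct": [], "neutral": [], "incorrect": []}
    for doc_id, lab in zip(base.doc_ids, labels):
        if lab == correct_label:
            tiers["correct"].append(doc_id)
        elif lab == "neutral":
            tiers["neutral"].append(doc_id)
        else:
            tiers["incorrect"].append(doc_id)
    ordered = tiers["correct"] + tiers["neutral"] + tiers["incorrect"]
    n = len(ordered)
    entries = [(d, float(n - i)) for i, d in enumerate(ordered)]
    return Ranking(base.topic_id, entries, run_tag=base.run_tag)


def supportiveness_rerank(
    topic: Topic,
    base: Ranking,
    checkers: Sequence[ClaimCheckerContract],
    corpus: Mapping[str, Document],
    k: int = DEFAULT_VOTE_K,
    rrf_k: float = DEFAULT_RRF_K,
) -> Ranking:
    """Per checker: label base's documents, infer the stance, tier-rerank;
    then fuse the per-checker rankings with RRF."""
    if not checkers:
        raise ValueError("need at least one claim checker")
    if not base.entries:
        return base
    tiered: list[Ranking] = []
    for checker in checkers:
        labels = []
        for doc_id in base.doc_ids:
            try:
                lab, _conf = checker.label(topic, corpus[doc_id])
            except Exception as exc:
                name = getattr(checker, "name", type(checker).__name__)
                raise RuntimeError(
                    f"claim checker {name} failed on doc {doc_id} "
                    f"(topic {topic.topic_id}): {exc}"
                ) from exc
            labels.append(lab)
        decision = infer_topic_stance(labels, k=k)
        tiered.append(tier_rerank(base, labels, decision))
    return rrf(tiered, rrf_k=rrf_k)
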