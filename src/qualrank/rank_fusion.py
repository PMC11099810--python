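"""Rank fusion: reciprocal rank fusion, weighted linear combination, ensemble
and depth-restricted reranking, and the weight-sweep experiment.

Reciprocal rank fusion (RRF) scores each document by ``sum over lists of
1 / (k + rank)`` with the canonical constant k=60; it is the default way the
pipeline combines rankings (the two BM25 indices, the per-model reranked
lists, and the per-dimension rankings).  The weighted linear combination
min-max normalizes each list's scores to [0, 1] and sums them with per-list
weights, which supports the quality-control experiment of sweeping one
model's weight while holding the others fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .benchmark_io import Document, Ranking, Topic

DEFAULT_RRF_K = 60.0


@dataclass(frozen=True)
class FusionConfig:
    rrf_k: float = DEFAULT_RRF_K
    weights: tuple[float, ...] = ()
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.weights and not any(w > 0 for w in self.weights):
            raise ValueError("at least one weight must be > 0")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")


def _check_same_topic(rankings: Sequence[Ranking]) -> str:
    if not rankings:
        raise ValueError("need at least one ranking")
    topic_ids = {r.topic_id for r in rankings}
    if len(topic_ids) != 1:
        raise ValueError(f"rankings mix topics: {sorted(topic_ids)}")
    return rankings[0].topic_id


def rrf(rankings: Sequence[Ranking], rrf_k: float = DEFAULT_RRF_K) -> Ranking:
    """Reciprocal rank fusion: score(doc) = sum over lists of 1/(k + rank).

    A document absent from a list contributes 0 from it.  Output is sorted by
    fused score descending, doc_id ascending.
    """
    topic_id = _check_same_topic(rankings)
    scores: dict[str, float] = {}
    for ranking in rankings:
        for rank, doc_id in enumerate(ranking.doc_ids, start=1):
            scores[doc_id] = scores.get(doc_id, 0.0) + 1.0 / (rrf_k + rank)
    return Ranking.from_scores(topic_id, scores, run_tag="rrf")


def rerank_by_scorer(
    base: Ranking,
    scorer,
    topic: Topic,
    corpus: Mapping[str, Document],
) -> Ranking:
    """Full reordering of base's documents by one scorer's (topic, doc) score."""
    scores: dict[str, float] = {}
    for doc_id in base.doc_ids:
        try:
            scores[doc_id] = float(scorer.score(topic, corpus[doc_id]))
        except Exception as exc:
            name = getattr(scorer, "name", type(scorer).__name__)
            raise RuntimeError(
                f"scorer {name} failed on doc {doc_id} (topic {topic.topic_id}): {exc}"
            ) from exc
    return Ranking.from_scores(base.topic_id, scores, run_tag="scored")


def ensemble_rerank(
    base: Ranking,
    scorers: Sequence,
    topic: Topic,
    corpus: Mapping[str, Document],
    rrf_k: float = DEFAULT_RRF_K,
) -> Ranking:
    """Rerank base by each scorer, then fuse the reorderings with RRF.

    Every scorer induces a full reordering of base's document set; the result
    covers exactly that set.
    """
    if not scorers:
        raise ValueError("need at least one scorer")
    reordered = [rerank_by_scorer(base, s, topic, corpus) for s in scorers]
    return rrf(reordered, rrf_k=rrf_k)


def weighted_combine(
    rankings: Sequence[Ranking],
    weights: Sequence[float],
    normalization: str = "minmax",
) -> Ranking:
    """Linear combination of score-normalized rankings.

    Each list's scores are min-max normalized to [0, 1] (a constant-score list
    maps to all 1); the combined score of a document is the weighted sum of
    its normalized scores, counting 0 for lists it is absent from.
    ``normalization="sum"`` divides by the score total instead.
    """
    topic_id = _check_same_topic(rankings)
    if len(weights) != len(rankings):
        raise ValueError("one weight per ranking required")
    FusionConfig(weights=tuple(weights))
    combined: dict[str, float] = {}
    for ranking, w in zip(rankings, weights):
        if not ranking.entries:
            continue
        values = [s for _, s in ranking.entries]
        if normalization == "minmax":
            lo, hi = min(values), max(values)
            span = hi - lo
            norm = {
                d: ((s - lo) / span if span > 0 else 1.0)
                for d, s in ranking.entries
            }
        elif normalization == "sum":
            total = sum(values)
            norm = {
                d: (s / total if total > 0 else 1.0 / len(values))
                for d, s in ranking.entries
            }
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        for d, v in norm.items():
            combined[d] = combined.get(d, 0.0) + w * v
    return Ranking.from_scores(topic_id, combined, run_tag="linear")


def weight_sweep(
    rankings: Sequence[Ranking],
    vary_index: int,
    grid: Sequence[float],
    eval_fn: Callable[[Ranking], float],
    fixed_weight: float = 0.33,
) -> list[tuple[float, float]]:
    """Sweep one ranking's weight over ``grid`` holding the others at
    ``fixed_weight``; evaluate each combination with ``eval_fn``.

    Returns the (weight, metric) series.
    """
    if not 0 <= vary_index < len(rankings):
        raise ValueError(f"vary_index {vary_index} out of range")
    curve = []
    for w in grid:
        weights = [fixed_weight] * len(rankings)
        weights[vary_index] = w
        fused = weighted_combine(rankings, weights)
        curve.append((w, eval_fn(fused)))
    return curve


def depth_restricted_rerank(
    base: Ranking,
    rerankers: Sequence[Callable[[Ranking], Ranking]],
    depth: int,
    rrf_k: float = DEFAULT_RRF_K,
) -> Ranking:
    """Rerank only the top-``depth`` prefix of base.

    Each reranker reorders the prefix; the reordered prefixes and the original
    prefix are fused with RRF, and the suffix (ranks > depth) is appended
    untouched in its original order.  The top-depth *set* is never changed,
    only its internal order.  Output scores are re-derived as descending ranks.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0 or not base.entries:
        return base
    prefix = base.truncate(depth)
    lists = [prefix] + [r(prefix) for r in rerankers]
    for lst in lists[1:]:
        if set(lst.doc_ids) != set(prefix.doc_ids):
            raise ValueError("reranker changed the prefix document set")
    fused = rrf(lists, rrf_k=rrf_k)
    ordered = fused.doc_ids + [d for d, _ in base.entries[depth:]]
    n = len(ordered)
    entries = [(d, float(n - i)) for i, d in enumerate(ordered)]
    return Ranking(base.topic_id, entries, run_tag=base.run_tag)
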