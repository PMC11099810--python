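"""Help/harm compatibility evaluation based on truncated rank-biased overlap.

Quality-centred retrieval is scored by how *compatible* a system ranking R is
with an ideal ranking I built from the assessments: the truncated rank-biased
overlap (RBO)

    RBO(R, I; p, K) = (1 - p) * sum_{d=1..K} p^(d-1) * |R:d ∩ I:d| / d

where ``R:d`` is the length-d prefix (shorter when the list ends), ``p`` is
the searcher's patience and ``K`` the search depth.  Because ideal rankings
are often much shorter than K, the score is normalized by the ideal's
self-overlap:

    compatibility(R, I) = RBO(R, I) / RBO(I, I)      (0 when I is empty).

Splitting the assessments into helpful and harmful documents gives *help*
and *harm* compatibility; their difference (help-harm) measures how much more
helpful than harmful content a system surfaces.  No extrapolation term is
used: the sum is the plain finite series truncated at K.

Defaults are p=0.95 and K=1000; K=10 supports the per-document interpretation
of the scores (at depth 10, one extra helpful document moves help
compatibility by roughly ten points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .benchmark_io import Judgment, JudgmentSet, Ranking, Topic

DEFAULT_P = 0.95
DEFAULT_K = 1000
INTERPRETATION_K = 10


@dataclass(frozen=True)
class CompatibilityParams:
    """Searcher patience ``p`` in (0,1) and search depth ``K`` >= 1."""

    p: float = DEFAULT_P
    K: int = DEFAULT_K

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")


def truncated_rbo(R: Ranking, I: Ranking, p: float = DEFAULT_P, K: int = DEFAULT_K) -> float:
    """Finite rank-biased overlap of R against I, truncated at depth K.

    Lies in [0, 1 - p^K]; both rankings must be duplicate-free (guaranteed by
    the Ranking invariant).
    """
    CompatibilityParams(p=p, K=K)  # validates
    r_docs = R.doc_ids
    i_docs = I.doc_ids
    r_seen: set[str] = set()
    i_seen: set[str] = set()
    overlap = 0
    total = 0.0
    weight = 1.0 - p  # (1-p) * p^(d-1) at d=1
    for d in range(1, K + 1):
        if d <= len(r_docs):
            doc = r_docs[d - 1]
            if doc in i_seen:
                overlap += 1
            r_seen.add(doc)
        if d <= len(i_docs):
            # r_seen already contains this depth's R element, so the case
            # r_docs[d-1] == i_docs[d-1] is counted exactly once, here.
            doc = i_docs[d - 1]
            if doc in r_seen:
                overlap += 1
            i_seen.add(doc)
        total += weight * overlap / d
        weight *= p
    return total


def compatibility(R: Ranking, I: Ranking, p: float = DEFAULT_P, K: int = DEFAULT_K) -> float:
    """Truncated RBO of R against I, normalized by I's self-overlap.

    Returns 0 for an empty ideal (convention); result lies in [0, 1].
    """
    if not I.entries:
        return 0.0
    denom = truncated_rbo(I, I, p=p, K=K)
    return truncated_rbo(R, I, p=p, K=K) / denom


def ideal_ranking(
    judgment_set: JudgmentSet, topic: Topic | str, polarity: str
) -> Ranking:
    """Ideal ranking of one polarity's documents for a topic.

    All documents labeled ``polarity`` (helpful or harmful), ordered by
    usefulness grade descending, credibility grade descending, doc_id
    ascending.  May be empty (e.g. a topic without harmful documents).
    """
    if polarity not in ("helpful", "harmful"):
        raise ValueError(f"polarity must be helpful or harmful, got {polarity!r}")
    topic_id = topic if isinstance(topic, str) else topic.topic_id
    docs = [
        j
        for j in judgment_set.for_topic(topic_id)
        if j.preference == polarity
    ]
    docs.sort(
        key=lambda j: (
            -(j.usefulness or 0),
            -(j.credibility if j.credibility is not None else 0),
            j.doc_id,
        )
    )
    entries = [(j.doc_id, float(len(docs) - i)) for i, j in enumerate(docs)]
    return Ranking(topic_id=topic_id, entries=entries, run_tag=f"ideal_{polarity}")


@dataclass
class TopicCompatibility:
    topic_id: str
    stance: str
    help: float
    harm: float

    @property
    def help_harm(self) -> float:
        return self.help - self.harm


@dataclass
class CompatibilityReport:
    """Per-topic help/harm compatibility and unweighted partition means.

    Partitions are ``helpful_T`` (helpful-stance topics), ``unhelpful_T`` and
    ``all_T``; ``help_harm`` equals ``help - harm`` per topic and in every
    aggregate.
    """

    per_topic: list[TopicCompatibility] = field(default_factory=list)
    params: CompatibilityParams = field(default_factory=CompatibilityParams)

    def _partition(self, which: str) -> list[TopicCompatibility]:
        if which == "all_T":
            return self.per_topic
        stance = {"helpful_T": "helpful", "unhelpful_T": "unhelpful"}[which]
        return [t for t in self.per_topic if t.stance == stance]

    def mean(self, metric: str, partition: str = "all_T") -> float:
        rows = self._partition(partition)
        if not rows:
            return float("nan")
        return sum(getattr(t, metric) for t in rows) / len(rows)

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            part: {
                "help": self.mean("help", part),
                "harm": self.mean("harm", part),
                "help_harm": self.mean("help_harm", part),
            }
            for part in ("helpful_T", "unhelpful_T", "all_T")
        }


def help_harm_report(
    runs: Sequence[Ranking],
    judgment_set: JudgmentSet,
    topics: Sequence[Topic],
    params: CompatibilityParams | None = None,
) -> CompatibilityReport:
    """Evaluate one run (a list of per-topic rankings) for help and harm.

    Per topic: help = compatibility(R, ideal helpful), harm = compatibility(R,
    ideal harmful).  Every run topic must have judgments.
    """
    params = params or CompatibilityParams()
    stance_by_topic = {t.topic_id: t for t in topics}
    judged = set(judgment_set.topic_ids())
    missing = [r.topic_id for r in runs if r.topic_id not in judged]
    if missing:
        raise ValueError(f"run topics absent from qrels: {sorted(missing)}")
    report = CompatibilityReport(params=params)
    for r in sorted(runs, key=lambda r: r.topic_id):
        topic = stance_by_topic.get(r.topic_id)
        stance = topic.stance if topic else "unknown"
        i_help = ideal_ranking(judgment_set, r.topic_id, "helpful")
        i_harm = ideal_ranking(judgment_set, r.topic_id, "harmful")
        report.per_topic.append(
            TopicCompatibility(
                topic_id=r.topic_id,
                stance=stance,
                help=compatibility(r, i_help, p=params.p, K=params.K),
                harm=compatibility(r, i_harm, p=params.p, K=params.K),
            )
        )
    return report


# ---------------------------------------------------------------------------
# nDCG
# ---------------------------------------------------------------------------

def ndcg(
    R: Ranking,
    judgment_set: JudgmentSet,
    polarity: str = "helpful",
    depth: int = DEFAULT_K,
) -> float:
    """Normalized discounted cumulative gain restricted to one polarity.

    Gains are the usefulness grades of documents labeled ``polarity``; all
    other documents gain 0.  DCG uses gain / log2(rank + 1); the ideal DCG
    sorts the polarity's gains descending.  Returns 0 when the ideal DCG is 0.
    """

    def gain(j: Judgment) -> float:
        return float(j.usefulness or 0) if j.preference == polarity else 0.0

    dcg = 0.0
    for rank, doc_id in enumerate(R.doc_ids[:depth], start=1):
        dcg += gain(judgment_set.get(R.topic_id, doc_id)) / math.log2(rank + 1)
    ideal_gains = sorted(
        (gain(j) for j in judgment_set.for_topic(R.topic_id)), reverse=True
    )
    idcg = sum(
        g / math.log2(rank + 1)
        for rank, g in enumerate(ideal_gains[:depth], start=1)
    )
    return dcg / idcg if idcg > 0 else 0.0


# ---------------------------------------------------------------------------
# Depth-10 interpretation
# ---------------------------------------------------------------------------

@dataclass
class Depth10Report:
    """Help/harm compatibility at search depth 10 plus top-10 label counts.

    At this depth a difference of one helpful document in the top 10
    corresponds to roughly ten points of help compatibility, so the scores
    can be read as document counts.
    """

    report: CompatibilityReport
    mean_helpful_in_top10: float
    mean_harmful_in_top10: float


def interpret_depth10(
    runs: Sequence[Ranking],
    judgment_set: JudgmentSet,
    topics: Sequence[Topic],
    p: float = DEFAULT_P,
) -> Depth10Report:
    """Evaluate a run at K=10 and count labeled documents in each top 10."""
    params = CompatibilityParams(p=p, K=INTERPRETATION_K)
    report = help_harm_report(runs, judgment_set, topics, params=params)
    n_help = n_harm = 0
    for r in runs:
        for doc_id in r.doc_ids[:INTERPRETATION_K]:
            label = judgment_set.get(r.topic_id, doc_id).preference
            if label == "helpful":
                n_help += 1
            elif label == "harmful":
                n_harm += 1
    n = max(len(runs), 1)
    return Depth10Report(
        report=report,
        mean_helpful_in_top10=n_help / n,
        mean_harmful_in_top10=n_harm / n,
    )
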