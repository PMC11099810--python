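"""Domain data model and readers/writers for topics, runs, and multidimensional qrels.

The data model mirrors quality-centred retrieval benchmarks in the style of the
TREC Health Misinformation track: each topic is a health question with a
ground-truth stance (the intervention is helpful or unhelpful), and each judged
(topic, document) pair carries graded usefulness, a supportiveness level
(supportive / dissuasive / neutral) and a credibility grade, from which a
helpful / harmful / neither preference label is derived.

File formats are plain text: runs in the 6-column TREC run format, qrels as
whitespace-separated columns (two dialects), topics as a JSON array, and the
corpus as JSON lines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

# Stances a topic can take.  "unknown" marks the automatic-run setting: the
# stance must never be consumed by ranking code, only by evaluation/synthesis.
STANCES = ("helpful", "unhelpful", "unknown")
SUPPORTIVENESS_LEVELS = ("supportive", "dissuasive", "neutral", "unjudged")
PREFERENCE_LABELS = ("helpful", "harmful", "neither")

#: Default grade vocabularies (usefulness 0=not useful .. 2=very useful;
#: credibility 0=not credible, 1=credible).
USEFULNESS_GRADES = (0, 1, 2)
CREDIBILITY_GRADES = (0, 1)


@dataclass(frozen=True)
class Topic:
    """A health question: keyword query, natural-language description, stance."""

    topic_id: str
    query: str
    description: str = ""
    stance: str = "unknown"

    def __post_init__(self) -> None:
        if self.stance not in STANCES:
            raise ValueError(f"unknown stance {self.stance!r} for topic {self.topic_id}")


@dataclass(frozen=True)
class Document:
    """A web document: plain text plus optional URL, timestamp and raw HTML."""

    doc_id: str
    text: str
    url: str = ""
    timestamp: str = ""
    html: str | None = None


@dataclass(frozen=True)
class Judgment:
    """Graded multidimensional assessment of one (topic, document) pair.

    ``usefulness`` and ``credibility`` are ``None`` when unjudged;
    ``supportiveness`` uses the explicit level ``"unjudged"``.
    """

    topic_id: str
    doc_id: str
    usefulness: int | None = None
    supportiveness: str = "unjudged"
    credibility: int | None = None
    preference: str = "neither"

    def __post_init__(self) -> None:
        if self.supportiveness not in SUPPORTIVENESS_LEVELS:
            raise ValueError(f"bad supportiveness {self.supportiveness!r}")
        if self.preference not in PREFERENCE_LABELS:
            raise ValueError(f"bad preference label {self.preference!r}")


_UNJUDGED = object()


class JudgmentSet:
    """Judgments keyed by (topic_id, doc_id).

    Lookup of an unjudged pair returns an explicit "unjudged" judgment, never
    an error, so evaluation code can treat pooled and unpooled documents
    uniformly.
    """

    def __init__(self, judgments: Iterable[Judgment] = (), dialect: str = "multidim"):
        self.dialect = dialect
        self._by_pair: dict[tuple[str, str], Judgment] = {}
        for j in judgments:
            self.add(j)

    def add(self, judgment: Judgment) -> None:
        key = (judgment.topic_id, judgment.doc_id)
        if key in self._by_pair:
            raise ValueError(f"duplicate judgment for pair {key}")
        self._by_pair[key] = judgment

    def get(self, topic_id: str, doc_id: str) -> Judgment:
        return self._by_pair.get(
            (topic_id, doc_id), Judgment(topic_id=topic_id, doc_id=doc_id)
        )

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self):
        return iter(self._by_pair.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_pair

    def topic_ids(self) -> list[str]:
        return sorted({j.topic_id for j in self})

    def for_topic(self, topic_id: str) -> list[Judgment]:
        return [j for j in self if j.topic_id == topic_id]


@dataclass
class Ranking:
    """An ordered, scored document list for one topic.

    Ranks are 1-based; scores are non-increasing with rank; doc_ids are unique.
    """

    topic_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)
    run_tag: str = "run"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev = None
        for doc_id, score in self.entries:
            if doc_id in seen:
                raise ValueError(f"duplicate doc {doc_id} in ranking {self.topic_id}")
            seen.add(doc_id)
            if prev is not None and score > prev:
                raise ValueError(
                    f"scores must be non-increasing in ranking {self.topic_id}"
                )
            prev = score

    @classmethod
    def from_scores(
        cls, topic_id: str, scores: Mapping[str, float], run_tag: str = "run"
    ) -> "Ranking":
        """Canonical construction: sort by score descending, doc_id ascending."""
        entries = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(topic_id=topic_id, entries=entries, run_tag=run_tag)

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def truncate(self, n: int) -> "Ranking":
        return Ranking(self.topic_id, list(self.entries[:n]), self.run_tag)


# ---------------------------------------------------------------------------
# TREC run files
# ---------------------------------------------------------------------------

def read_run(path) -> list[Ranking]:
    """Read a 6-column TREC run file into one :class:`Ranking` per topic.

    The rank column is re-derived from the stored scores (score descending,
    doc_id ascending), not trusted.
    """
    per_topic: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            topic_id, _q0, doc_id, _rank, score_s, _tag = parts
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad score {score_s!r}") from exc
            scores = per_topic.setdefault(topic_id, {})
            if doc_id in scores:
                raise ValueError(
                    f"{path}:{lineno}: duplicate document {doc_id} for topic {topic_id}"
                )
            scores[doc_id] = score
    return [
        Ranking.from_scores(t, scores, run_tag="run")
        for t, scores in sorted(per_topic.items())
    ]


def write_run(rankings: Sequence[Ranking], path, tag: str = "qualrank") -> None:
    """Write rankings in canonical 6-column TREC run format.

    Topics are emitted in ascending topic_id order, ranks start at 1, scores
    are printed with 6 decimals.  Empty rankings are omitted with a warning.
    """
    if not rankings:
        raise ValueError("no rankings to write")
    with open(path, "w", encoding="utf-8") as fh:
        for ranking in sorted(rankings, key=lambda r: r.topic_id):
            if not ranking.entries:
                warnings.warn(f"topic {ranking.topic_id}: empty ranking omitted")
                logger.warning("topic %s: empty ranking omitted", ranking.topic_id)
                continue
            for rank, (doc_id, score) in enumerate(ranking.entries, start=1):
                fh.write(f"{ranking.topic_id} Q0 {doc_id} {rank} {score:.6f} {tag}\n")


# ---------------------------------------------------------------------------
# Qrels
# ---------------------------------------------------------------------------

_PREFERENCE_CODES = {"1": "helpful", "-1": "harmful", "0": "neither"}
_PREFERENCE_TO_CODE = {v: k for k, v in _PREFERENCE_CODES.items()}


def read_qrels(path, dialect: str = "multidim") -> JudgmentSet:
    """Read a qrels file in either the ``multidim`` or ``preference`` dialect.

    multidim rows: ``topic doc usefulness supportiveness credibility`` with
    usefulness in {0,1,2}, supportiveness a level word, credibility in
    {0,1,unjudged}.  preference rows: ``topic doc label`` with label in
    {1 (helpful), -1 (harmful), 0 (neither)}.
    """
    if dialect not in ("multidim", "preference"):
        raise ValueError(f"unknown qrels dialect {dialect!r}")
    js = JudgmentSet(dialect=dialect)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                if dialect == "multidim":
                    if len(parts) != 5:
                        raise ValueError(f"expected 5 columns, got {len(parts)}")
                    topic_id, doc_id, use_s, supp, cred_s = parts
                    usefulness = int(use_s)
                    if usefulness not in USEFULNESS_GRADES:
                        raise ValueError(f"usefulness grade {usefulness} out of range")
                    if supp not in SUPPORTIVENESS_LEVELS:
                        raise ValueError(f"bad supportiveness {supp!r}")
                    if cred_s == "unjudged":
                        credibility = None
                    else:
                        credibility = int(cred_s)
                        if credibility not in CREDIBILITY_GRADES:
                            raise ValueError(f"credibility grade {credibility} out of range")
                    js.add(
                        Judgment(
                            topic_id=topic_id,
                            doc_id=doc_id,
                            usefulness=usefulness,
                            supportiveness=supp,
                            credibility=credibility,
                        )
                    )
                else:
                    if len(parts) != 3:
                        raise ValueError(f"expected 3 columns, got {len(parts)}")
                    topic_id, doc_id, code = parts
                    if code not in _PREFERENCE_CODES:
                        raise ValueError(f"bad preference code {code!r}")
                    js.add(
                        Judgment(
                            topic_id=topic_id,
                            doc_id=doc_id,
                            preference=_PREFERENCE_CODES[code],
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return js


def write_qrels(judgment_set: JudgmentSet, path) -> None:
    """Write qrels in the set's dialect, sorted by (topic_id, doc_id)."""
    rows = sorted(judgment_set, key=lambda j: (j.topic_id, j.doc_id))
    with open(path, "w", encoding="utf-8") as fh:
        for j in rows:
            if judgment_set.dialect == "multidim":
                cred = "unjudged" if j.credibility is None else str(j.credibility)
                use = 0 if j.usefulness is None else j.usefulness
                fh.write(f"{j.topic_id} {j.doc_id} {use} {j.supportiveness} {cred}\n")
            else:
                fh.write(f"{j.topic_id} {j.doc_id} {_PREFERENCE_TO_CODE[j.preference]}\n")


# ---------------------------------------------------------------------------
# Topics and corpus
# ---------------------------------------------------------------------------

def read_topics(path) -> list[Topic]:
    """Read topics from a JSON array of {topic_id, query, description, stance}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        Topic(
            topic_id=str(r["topic_id"]),
            query=r["query"],
            description=r.get("description", ""),
            stance=r.get("stance", "unknown"),
        )
        for r in raw
    ]


def write_topics(topics: Sequence[Topic], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "topic_id": t.topic_id,
                    "query": t.query,
                    "description": t.description,
                    "stance": t.stance,
                }
                for t in topics
            ],
            fh,
            indent=1,
        )
        fh.write("\n")


def read_corpus(path) -> dict[str, Document]:
    """Read a JSON-lines corpus of {doc_id, text, url, timestamp, html}."""
    corpus: dict[str, Document] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            r = json.loads(line)
            doc = Document(
                doc_id=str(r["doc_id"]),
                text=r["text"],
                url=r.get("url", ""),
                timestamp=r.get("timestamp", ""),
                html=r.get("html"),
            )
            if doc.doc_id in corpus:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id}")
            corpus[doc.doc_id] = doc
    return corpus


def write_corpus(corpus: Mapping[str, Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in sorted(corpus):
            d = corpus[doc_id]
            rec = {"doc_id": d.doc_id, "text": d.text, "url": d.url, "timestamp": d.timestamp}
            if d.html is not None:
                rec["html"] = d.html
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Preference-label derivation and 2019→2021 grade mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelRuleConfig:
    """Configurable rule deriving helpful/harmful labels from graded judgments.

    A document is considered at all only if its usefulness grade reaches
    ``useful_threshold`` (the track's hierarchical annotation: only useful
    documents are assessed further).  Among useful documents, one that agrees
    with the topic stance (supports a helpful treatment, or dissuades from an
    unhelpful one) is helpful; one that opposes it is harmful; neutral or
    unjudged supportiveness yields neither.
    """

    useful_threshold: int = 1
    #: (topic stance, supportiveness) -> preference label
    rule: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: {
            ("helpful", "supportive"): "helpful",
            ("helpful", "dissuasive"): "harmful",
            ("helpful", "neutral"): "neither",
            ("unhelpful", "supportive"): "harmful",
            ("unhelpful", "dissuasive"): "helpful",
            ("unhelpful", "neutral"): "neither",
        }
    )


def derive_preference_labels(
    judgment_set: JudgmentSet,
    topics: Sequence[Topic],
    rule_config: LabelRuleConfig | None = None,
) -> JudgmentSet:
    """Return a new JudgmentSet with helpful/harmful/neither labels filled in.

    Requires a ground-truth stance for every judged topic; a topic with
    stance ``unknown`` makes the labels undefined and raises.
    """
    cfg = rule_config or LabelRuleConfig()
    stance_by_topic = {t.topic_id: t.stance for t in topics}
    out = JudgmentSet(dialect=judgment_set.dialect)
    for j in judgment_set:
        stance = stance_by_topic.get(j.topic_id)
        if stance is None:
            raise ValueError(f"no topic provided for judged topic {j.topic_id}")
        if stance == "unknown":
            raise ValueError(
                f"topic {j.topic_id} has unknown stance; preference labels undefined"
            )
        useful = j.usefulness is not None and j.usefulness >= cfg.useful_threshold
        if useful and j.supportiveness in ("supportive", "dissuasive", "neutral"):
            label = cfg.rule.get((stance, j.supportiveness), "neither")
        else:
            label = "neither"
        out.add(replace(j, preference=label))
    return out


#: 2019 benchmark grade vocabularies (relevance / effectiveness / credibility)
#: and their translation onto the 2021 dimensions.  Highly relevant becomes
#: very useful; effective becomes supportive, ineffective dissuasive;
#: credibility grades carry over unchanged.
_RELEVANCE_2019_TO_USEFULNESS = {
    "highly_relevant": 2,
    "relevant": 1,
    "not_relevant": 0,
}
_EFFECTIVENESS_2019_TO_SUPPORTIVENESS = {
    "effective": "supportive",
    "ineffective": "dissuasive",
    "neutral": "neutral",
    "unjudged": "unjudged",
}


def map_2019_to_2021(judgment_2019: "Judgment | Mapping[str, object]") -> Judgment:
    """Map a 2019-style (relevance, effectiveness, credibility) record onto
    the 2021 (usefulness, supportiveness, credibility) dimensions.

    Accepts a mapping with keys ``topic_id, doc_id, relevance, effectiveness,
    credibility``; an already-mapped :class:`Judgment` is returned unchanged,
    making the operation idempotent.
    """
    if isinstance(judgment_2019, Judgment):
        return judgment_2019
    topic_id = str(judgment_2019["topic_id"])
    doc_id = str(judgment_2019["doc_id"])
    relevance = judgment_2019["relevance"]
    effectiveness = judgment_2019["effectiveness"]
    credibility = judgment_2019.get("credibility")
    if relevance not in _RELEVANCE_2019_TO_USEFULNESS:
        raise ValueError(f"unmapped relevance grade {relevance!r}")
    if effectiveness not in _EFFECTIVENESS_2019_TO_SUPPORTIVENESS:
        raise ValueError(f"unmapped effectiveness grade {effectiveness!r}")
    if credibility is not None and credibility not in CREDIBILITY_GRADES:
        raise ValueError(f"unmapped credibility grade {credibility!r}")
    return Judgment(
        topic_id=topic_id,
        doc_id=doc_id,
        usefulness=_RELEVANCE_2019_TO_USEFULNESS[relevance],
        supportiveness=_EFFECTIVENESS_2019_TO_SUPPORTIVENESS[effectiveness],
        credibility=credibility,
    )
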