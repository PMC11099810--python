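"""Preprocessing phase: in-memory Okapi BM25, silver topics, known-item tuning.

The candidate-selection step of the pipeline retrieves, per topic, the top
``n_docs`` documents from two BM25 parameterizations of the same corpus — a
default index (k1=1.2, b=0.75) and one tuned by grid search on automatically
generated "silver" topics in a known-item search protocol (the query generated
from a document should retrieve that document at rank 1) — and fuses the two
result lists with reciprocal rank fusion.

The BM25 variant is Okapi with the non-negative IDF
``ln((N - df + 0.5) / (df + 0.5) + 1)``.  Tokenization is lowercase splitting
on non-alphanumeric characters, with no stemming or stopword removal; a
different tokenizer can be passed to :class:`Bm25Index`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .benchmark_io import Document, Ranking, Topic

_TOKEN_RE = re.compile(r"[a-z0-9]+")

DEFAULT_K1 = 1.2
DEFAULT_B = 0.75
DEFAULT_N_DOCS = 10_000
#: Grid-search defaults for known-item tuning (k1 outer, b inner, row-major).
DEFAULT_K1_GRID = (0.6, 0.9, 1.2, 1.5, 1.8)
DEFAULT_B_GRID = (0.3, 0.5, 0.75, 0.9)


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens."""
    return _TOKEN_RE.findall(text.lower())


class Bm25Index:
    """In-memory inverted index answering Okapi BM25 scores.

    Term statistics (postings, document lengths) are parameter-independent, so
    a single index can be scored under any (k1, b) — which is what the
    known-item grid search exploits.
    """

    def __init__(
        self,
        corpus: Mapping[str, Document],
        k1: float = DEFAULT_K1,
        b: float = DEFAULT_B,
        tokenizer: Callable[[str], list[str]] = tokenize,
    ):
        if not corpus:
            raise ValueError("empty corpus")
        if k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {k1}")
        if not 0.0 <= b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {b}")
        self.k1 = k1
        self.b = b
        self.tokenizer = tokenizer
        self.doc_ids: list[str] = sorted(corpus)
        self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}
        n = len(self.doc_ids)
        self.doc_len = np.zeros(n, dtype=np.float64)
        # term -> (doc index array, term frequency array)
        self.postings: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        raw: dict[str, dict[int, int]] = {}
        for i, doc_id in enumerate(self.doc_ids):
            text = corpus[doc_id].text
            if not text:
                raise ValueError(f"document {doc_id} has empty text")
            tokens = tokenizer(text)
            self.doc_len[i] = len(tokens)
            for tok in tokens:
                raw.setdefault(tok, {}).setdefault(i, 0)
                raw[tok][i] += 1
        for term, tfs in raw.items():
            idx = np.fromiter(tfs.keys(), dtype=np.int64, count=len(tfs))
            tf = np.fromiter(tfs.values(), dtype=np.float64, count=len(tfs))
            order = np.argsort(idx)
            self.postings[term] = (idx[order], tf[order])
        self.n_docs = n
        self.avg_doc_len = float(self.doc_len.mean())
        if self.avg_doc_len <= 0:
            raise ValueError("average document length must be > 0")

    def idf(self, term: str) -> float:
        df = len(self.postings[term][0]) if term in self.postings else 0
        return math.log((self.n_docs - df + 0.5) / (df + 0.5) + 1.0)

    def score_all(
        self, query_text: str, k1: float | None = None, b: float | None = None
    ) -> np.ndarray:
        """BM25 score of every document for the query (dense vector)."""
        k1 = self.k1 if k1 is None else k1
        b = self.b if b is None else b
        scores = np.zeros(self.n_docs, dtype=np.float64)
        norm = k1 * (1.0 - b + b * self.doc_len / self.avg_doc_len)
        for term in self.tokenizer(query_text):
            if term not in self.postings:
                continue
            idx, tf = self.postings[term]
            scores[idx] += self.idf(term) * tf * (k1 + 1.0) / (tf + norm[idx])
        return scores


def build_index(
    corpus: Mapping[str, Document],
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> Bm25Index:
    """Build a BM25 index over the corpus with the given parameters."""
    return Bm25Index(corpus, k1=k1, b=b, tokenizer=tokenizer)


def search(
    index: Bm25Index,
    query_text: str,
    n_docs: int = DEFAULT_N_DOCS,
    topic_id: str = "q",
    k1: float | None = None,
    b: float | None = None,
) -> Ranking:
    """Top-``n_docs`` documents by BM25 score (ties broken by doc_id).

    Documents with zero score (no query term in common) are not returned, so
    a query matching nothing yields an empty ranking.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    scores = index.score_all(query_text, k1=k1, b=b)
    hit = np.flatnonzero(scores > 0.0)
    entries = sorted(
        ((index.doc_ids[i], float(scores[i])) for i in hit),
        key=lambda kv: (-kv[1], kv[0]),
    )[:n_docs]
    return Ranking(topic_id=topic_id, entries=entries, run_tag="bm25")


# ---------------------------------------------------------------------------
# Silver topics and known-item tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SilverTopic:
    """An automatically generated topic targeting a known document."""

    target_doc_id: str
    query: str
    description: str = ""


def _tfidf_keyword_generator(index: Bm25Index, n_keywords: int = 5):
    """Default query generator: the document's top-TF-IDF keywords."""

    def generate(doc: Document) -> str:
        counts: dict[str, int] = {}
        for tok in index.tokenizer(doc.text):
            counts[tok] = counts.get(tok, 0) + 1
        scored = sorted(
            ((tf * index.idf(t), t) for t, tf in counts.items()),
            key=lambda st: (-st[0], st[1]),
        )
        return " ".join(t for _, t in scored[:n_keywords])

    return generate


def first_sentence(doc: Document) -> str:
    """Default description generator: the document's first sentence."""
    m = re.split(r"(?<=[.!?])\s+", doc.text.strip(), maxsplit=1)
    return m[0] if m else doc.text


def identity_query(doc: Document) -> str:
    """Query generator returning the full document text (self-retrieval)."""
    return doc.text


def generate_silver_topics(
    corpus: Mapping[str, Document],
    n: int,
    query_generator: Callable[[Document], str] | None = None,
    description_generator: Callable[[Document], str] = first_sentence,
    seed: int = 0,
) -> list[SilverTopic]:
    """Sample ``n`` distinct documents and generate a silver topic for each.

    The default query generator extracts top-TF-IDF keywords; the default
    description generator takes the first sentence.  Reproducible under
    ``seed``.
    """
    if n > len(corpus):
        raise ValueError(f"cannot sample {n} silver topics from {len(corpus)} docs")
    rng = np.random.default_rng(seed)
    doc_ids = sorted(corpus)
    chosen = rng.choice(len(doc_ids), size=n, replace=False)
    if query_generator is None:
        query_generator = _tfidf_keyword_generator(build_index(corpus))
    topics = []
    for i in sorted(chosen):
        doc = corpus[doc_ids[i]]
        topics.append(
            SilverTopic(
                target_doc_id=doc.doc_id,
                query=query_generator(doc),
                description=description_generator(doc),
            )
        )
    return topics


def known_item_success_rate(
    index: Bm25Index,
    silver_topics: Sequence[SilverTopic],
    k1: float | None = None,
    b: float | None = None,
) -> float:
    """Fraction of silver topics whose target document ranks first."""
    if not silver_topics:
        raise ValueError("empty silver-topic list")
    hits = 0
    for st in silver_topics:
        top = search(index, st.query, n_docs=1, k1=k1, b=b)
        if top.entries and top.entries[0][0] == st.target_doc_id:
            hits += 1
    return hits / len(silver_topics)


def tune_known_item(
    corpus: Mapping[str, Document],
    silver_topics: Sequence[SilverTopic],
    k1_grid: Sequence[float] = DEFAULT_K1_GRID,
    b_grid: Sequence[float] = DEFAULT_B_GRID,
) -> tuple[float, float, float]:
    """Grid-search (k1, b) maximizing known-item success at rank 1.

    Ties are broken by the first grid point in row-major order (k1 outer,
    b inner).  Returns ``(k1, b, success_rate)``.
    """
    if not k1_grid or not b_grid:
        raise ValueError("empty parameter grid")
    if not silver_topics:
        raise ValueError("empty silver-topic list")
    index = build_index(corpus)
    best: tuple[float, float, float] | None = None
    for k1 in k1_grid:
        for b in b_grid:
            rate = known_item_success_rate(index, silver_topics, k1=k1, b=b)
            if best is None or rate > best[2]:
                best = (k1, b, rate)
    return best


def preprocess(
    topic: Topic,
    index_default: Bm25Index,
    index_tuned: Bm25Index,
    n_docs: int = DEFAULT_N_DOCS,
    rrf_k: float = 60.0,
) -> Ranking:
    """Candidate selection: fuse default-parameter and tuned-parameter BM25
    result lists with reciprocal rank fusion, truncated to ``n_docs``.

    Only the topic's query text is consumed; the topic stance never is.
    """
    from .rank_fusion import rrf  # local import to avoid cycle

    r_default = search(index_default, topic.query, n_docs=n_docs, topic_id=topic.topic_id)
    r_tuned = search(index_tuned, topic.query, n_docs=n_docs, topic_id=topic.topic_id)
    fused = rrf([r_default, r_tuned], rrf_k=rrf_k)
    fused.run_tag = "H_P"
    return fused.truncate(n_docs)
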