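"""Synthetic miniature benchmark with planted quality structure, plus
fidelity-controlled mock scorers.

The generator emulates a quality-judged web-search benchmark: a set of health
topics with ground-truth stances (the default shape is 32 topics, 14 helpful
and 18 unhelpful), a small web-document corpus, and multidimensional qrels.
Per topic, each document is useful with probability ``p_useful``; useful
documents take a supportive / dissuasive / neutral stance (helpful-stance
topics are biased toward supportive documents, unhelpful-stance topics have
even odds, mirroring how real web content skews) and are credible with
probability ``p_credible``.  Document text is synthesized from topic
signature tokens plus shared filler vocabulary, with useful documents
carrying more signature occurrences, so lexical retrieval ranks useful
documents above filler on average; stance is additionally encoded by marker
tokens so keyword-level checkers are exercisable.

Mock scorers stand in for the neural reranking models: with probability
``fidelity`` they return the ground-truth-consistent score or label, and
otherwise a uniformly random one, deterministically per (topic, doc, seed).
Fidelity 1 reproduces the ground truth exactly; fidelity 0 is
label-independent noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .benchmark_io import (
    Document,
    Judgment,
    JudgmentSet,
    LabelRuleConfig,
    Topic,
    derive_preference_labels,
)

#: Default benchmark shape: 32 topics, 14 helpful / 18 unhelpful.
DEFAULT_N_TOPICS = 32
DEFAULT_FRACTION_HELPFUL = 14 / 32

SUPPORT_MARKER = "treatmentworks"
REFUTE_MARKER = "treatmentfails"


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted benchmark; generation is a pure function of
    (spec, seed)."""

    n_topics: int = DEFAULT_N_TOPICS
    fraction_helpful_topics: float = DEFAULT_FRACTION_HELPFUL
    docs_per_topic: int = 200
    #: probability a document of a topic is useful (on-topic and informative)
    p_useful: float = 0.2
    #: probability a useful, non-neutral doc on a helpful topic is supportive
    stance_bias_helpful: float = 0.75
    #: same for unhelpful topics (even odds by default)
    stance_bias_unhelpful: float = 0.5
    #: probability a useful doc is neutral (too thin to take a stance)
    p_neutral: float = 0.2
    p_credible: float = 0.5
    vocabulary_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_helpful_topics",
            "p_useful",
            "stance_bias_helpful",
            "stance_bias_unhelpful",
            "p_neutral",
            "p_credible",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_topics < 1 or self.docs_per_topic < 1 or self.vocabulary_size < 10:
            raise ValueError("n_topics, docs_per_topic, vocabulary_size too small")


def generate_benchmark(
    spec: BenchmarkSpec = BenchmarkSpec(),
) -> tuple[list[Topic], dict[str, Document], JudgmentSet]:
    """Generate (topics, corpus, qrels) with planted multidimensional grades.

    The returned judgment set covers every (topic, own-document) pair with
    usefulness, supportiveness and credibility grades and the derived
    helpful/harmful/neither preference labels.
    """
    rng = np.random.default_rng(spec.seed)
    filler = [f"w{k:04d}" for k in range(spec.vocabulary_size)]
    n_helpful = round(spec.n_topics * spec.fraction_helpful_topics)

    topics: list[Topic] = []
    corpus: dict[str, Document] = {}
    judgments = JudgmentSet(dialect="multidim")

    for t in range(spec.n_topics):
        topic_id = f"t{t + 1:03d}"
        stance = "helpful" if t < n_helpful else "unhelpful"
        signature = [f"sig{t + 1:03d}x{j}" for j in range(6)]
        topics.append(
            Topic(
                topic_id=topic_id,
                query=" ".join(signature[:3]),
                description=f"does intervention {signature[0]} help with condition {signature[1]}",
                stance=stance,
            )
        )
        bias = (
            spec.stance_bias_helpful if stance == "helpful" else spec.stance_bias_unhelpful
        )
        for i in range(spec.docs_per_topic):
            doc_id = f"{topic_id}d{i + 1:04d}"
            useful = rng.random() < spec.p_useful
            if useful:
                grade = 2 if rng.random() < 0.3 else 1
                if rng.random() < spec.p_neutral:
                    supp = "neutral"
                elif rng.random() < bias:
                    supp = "supportive"
                else:
                    supp = "dissuasive"
                n_sig = int(rng.integers(4, 7))
                tokens = list(rng.choice(signature, size=n_sig)) + list(
                    rng.choice(filler, size=25)
                )
                if supp == "supportive":
                    tokens += [SUPPORT_MARKER] * 3
                elif supp == "dissuasive":
                    tokens += [REFUTE_MARKER] * 3
            else:
                grade = 0
                supp = "neutral"
                tokens = [str(rng.choice(signature))] + list(rng.choice(filler, size=30))
            rng.shuffle(tokens)
            credible = int(rng.random() < spec.p_credible)
            corpus[doc_id] = Document(
                doc_id=doc_id,
                text=" ".join(tokens) + ".",
                url=f"https://{'trusted' if credible else 'site'}{i % 97}.example.com/{doc_id}",
                timestamp="2019-04-20T00:00:00Z",
            )
            judgments.add(
                Judgment(
                    topic_id=topic_id,
                    doc_id=doc_id,
                    usefulness=grade,
                    supportiveness=supp,
                    credibility=credible,
                )
            )

    labeled = derive_preference_labels(judgments, topics, LabelRuleConfig())
    return topics, corpus, labeled


# ---------------------------------------------------------------------------
# Mock scorers
# ---------------------------------------------------------------------------

DIMENSIONS = ("usefulness", "supportiveness", "credibility")


@dataclass(frozen=True)
class MockScorerSpec:
    """Dimension, fidelity in [0, 1], and seed of a mock reranking model."""

    dimension: str
    fidelity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError(f"fidelity must be in [0, 1], got {self.fidelity}")


def _pair_uniforms(spec: MockScorerSpec, topic_id: str, doc_id: str) -> tuple[float, float]:
    """Two deterministic U(0,1) draws per (scorer spec, topic, doc)."""
    key = f"{spec.seed}|{spec.dimension}|{spec.fidelity}|{topic_id}|{doc_id}"
    digest = hashlib.blake2b(key.encode(), digest_size=16).digest()
    u1 = int.from_bytes(digest[:8], "big") / 2**64
    u2 = int.from_bytes(digest[8:], "big") / 2**64
    return u1, u2


class MockScorer:
    """ScorerContract stand-in reading planted grades from the qrels."""

    def __init__(self, spec: MockScorerSpec, judgment_set: JudgmentSet):
        self.spec = spec
        self.judgments = judgment_set
        self.name = f"mock-{spec.dimension}-phi{spec.fidelity}-s{spec.seed}"

    def score(self, topic: Topic, doc: Document) -> float:
        u1, u2 = _pair_uniforms(self.spec, topic.topic_id, doc.doc_id)
        j = self.judgments.get(topic.topic_id, doc.doc_id)
        if self.spec.dimension == "usefulness":
            truth = float(j.usefulness or 0)
            noise = float(int(u2 * 3))  # uniform over {0, 1, 2}
        else:  # credibility
            truth = float(j.credibility or 0)
            noise = float(int(u2 * 2))  # uniform over {0, 1}
        return truth if u1 < self.spec.fidelity else noise


_TRUTH_TO_CLAIM = {
    "supportive": "supports",
    "dissuasive": "refutes",
    "neutral": "neutral",
    "unjudged": "neutral",
}
_CLAIM_LABELS = ("supports", "refutes", "neutral")


class MockClaimChecker:
    """ClaimCheckerContract stand-in reading planted stances from the qrels."""

    def __init__(self, spec: MockScorerSpec, judgment_set: JudgmentSet):
        self.spec = spec
        self.judgments = judgment_set
        self.name = f"mock-checker-phi{spec.fidelity}-s{spec.seed}"

    def label(self, topic: Topic, doc: Document) -> tuple[str, float]:
        u1, u2 = _pair_uniforms(self.spec, topic.topic_id, doc.doc_id)
        if u1 < self.spec.fidelity:
            j = self.judgments.get(topic.topic_id, doc.doc_id)
            return _TRUTH_TO_CLAIM[j.supportiveness], 1.0
        return _CLAIM_LABELS[int(u2 * 3)], 0.5


def mock_scorer(spec: MockScorerSpec, judgment_set: JudgmentSet):
    """Build the mock model for a dimension: a claim checker for
    supportiveness, a scorer for usefulness and credibility."""
    if spec.dimension == "supportiveness":
        return MockClaimChecker(spec, judgment_set)
    return MockScorer(spec, judgment_set)
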