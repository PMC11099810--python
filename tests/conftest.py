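import pytest

from qualrank import (
    BenchmarkSpec,
    Document,
    Judgment,
    JudgmentSet,
    Ranking,
    Topic,
    derive_preference_labels,
    generate_benchmark,
)


@pytest.fixture
def toy_corpus() -> dict[str, Document]:
    """Three tiny documents with overlapping vocabulary."""
    docs = [
        Document("dA", "fever sponge bath children fever"),
        Document("dB", "vitamin sun exposure skin"),
        Document("dC", "fever medicine children dose children"),
    ]
    return {d.doc_id: d for d in docs}


@pytest.fixture
def toy_topics() -> list[Topic]:
    return [
        Topic("101", "fever children", "does x help fever in children", "helpful"),
        Topic("102", "vitamin sun", "does vitamin help skin", "unhelpful"),
    ]


@pytest.fixture
def toy_judgments(toy_topics) -> JudgmentSet:
    js = JudgmentSet(dialect="multidim")
    rows = [
        ("101", "dA", 2, "supportive", 1),
        ("101", "dB", 0, "neutral", 0),
        ("101", "dC", 1, "dissuasive", 1),
        ("102", "dA", 1, "supportive", 0),
        ("102", "dB", 2, "dissuasive", 1),
    ]
    for t, d, u, s, c in rows:
        js.add(Judgment(t, d, usefulness=u, supportiveness=s, credibility=c))
    return derive_preference_labels(js, toy_topics)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted benchmark shared by integration-style tests."""
    spec = BenchmarkSpec(n_topics=6, docs_per_topic=80, seed=7)
    return generate_benchmark(spec)


def make_ranking(topic_id: str, doc_ids: list[str]) -> Ranking:
    """Ranking with scores derived from positions (descending)."""
    n = len(doc_ids)
    return Ranking(topic_id, [(d, float(n - i)) for i, d in enumerate(doc_ids)])


@pytest.fixture
def ranking_factory():
    return make_ranking
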