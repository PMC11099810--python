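"""Stance-aware reranking: vote on the topic, then tier the documents.

A claim checker labels each retrieved document as supporting, refuting or
neutral toward the topic's treatment claim. A majority vote over the top-k
labels decides the likely correct stance; documents agreeing with it are
moved up, neutral ones stay in the middle, disagreeing ones move down —
each tier preserving the original retrieval order.
"""

from qualrank import Ranking, infer_topic_stance, tier_rerank

base = Ranking("t1", [(d, float(9 - i)) for i, d in enumerate(
    ["d1", "d2", "d3", "d4", "d5", "d6"])])
labels = ["refutes", "supports", "neutral", "supports", "supports", "refutes"]

decision = infer_topic_stance(labels, k=6)
print(f"votes: supports={decision.supports_votes} refutes={decision.refutes_votes} "
      f"neutral={decision.neutral_votes} -> topic claim is {decision.stance}")

reranked = tier_rerank(base, labels, decision)
print(f"base order:     {base.doc_ids}")
print(f"tiered order:   {reranked.doc_ids}")
print("supporting docs (d2, d4, d5) now lead; the refuting ones (d1, d6) sink,")
print("and within each tier the original BM25 order is untouched.")
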