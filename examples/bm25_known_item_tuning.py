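"""Tuning BM25 parameters without human relevance judgments.

When no judged topics exist for a corpus, "silver" topics are generated
automatically from sampled documents, and (k1, b) are grid-searched by
known-item success: a parameter point is good if each silver query
retrieves its source document at rank 1.
"""

import numpy as np

from qualrank import Document, build_index, generate_silver_topics, search, tune_known_item
from qualrank.lexical_retrieval import known_item_success_rate

rng = np.random.default_rng(0)
vocab = [f"term{i:03d}" for i in range(400)]
corpus = {}
for i in range(150):
    doc_id = f"doc{i:03d}"
    words = rng.choice(vocab, size=40)
    corpus[doc_id] = Document(doc_id, " ".join(words))

silver = generate_silver_topics(corpus, n=40, seed=1)
print(f"generated {len(silver)} silver topics; first query: {silver[0].query!r}")

index = build_index(corpus)
default_rate = known_item_success_rate(index, silver)
k1, b, tuned_rate = tune_known_item(corpus, silver)
print(f"known-item success at defaults (k1=1.2, b=0.75): {default_rate:.2f}")
print(f"best grid point: k1={k1}, b={b} with success {tuned_rate:.2f}")

# The tuned index is then used for retrieval alongside the default one.
tuned_index = build_index(corpus, k1=k1, b=b)
top = search(tuned_index, silver[0].query, n_docs=3, topic_id="s0")
print(f"tuned index retrieves {top.doc_ids[0]} first for that query "
      f"(source was {silver[0].target_doc_id})")
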