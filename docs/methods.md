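# Methods

This note documents the model, the procedures, the parameter choices and
their rationale, what the synthetic benchmark does and does not emulate, and
the known limitations.

## Problem setting

Topics are consumer health questions of the form "does treatment X help
condition Y?", each with a ground-truth **stance**: *helpful* if the
treatment is effective per credible evidence, *unhelpful* otherwise.
Documents are judged along three dimensions:

- **usefulness** ∈ {0, 1, 2}: topical pertinence to the question;
- **supportiveness** ∈ {supportive, dissuasive, neutral}: the document's
  stance toward the treatment;
- **credibility** ∈ {0, 1}: trustworthiness of the source (a 1–5 assessor
  scale is binarized with 4–5 → 1).

A document is **helpful** when it is useful (grade ≥ 1) and its stance agrees
with the truth (supportive on a helpful topic, dissuasive on an unhelpful
one); it is **harmful** when useful and stance-opposed; otherwise *neither*.
These rules are configurable (`LabelRuleConfig`). Judgments from an older
schema (graded relevance + effectiveness labels) map losslessly onto this one
(`map_2019_to_2021`), and the mapping is idempotent.

## Evaluation: compatibility

For a system ranking `R` and a finite ideal ranking `I`, truncated rank-biased
overlap is

    RBO(R, I) = (1 − p) · Σ_{d=1..K} p^(d−1) · |R:d ∩ I:d| / d

and compatibility is `C(R, I) = RBO(R, I) / RBO(I, I)` (0 when `I` is empty).
The geometric weights model a searcher with patience `p` who keeps reading the
next result with probability `p`; normalization by the ideal's self-overlap
makes a perfect prefix score 1 regardless of how few judged documents exist.

- **help** = C(R, ideal of helpful docs), **harm** = C(R, ideal of harmful
  docs), headline metric **help − harm**.
- Ideal rankings order the polarity's documents by usefulness grade
  descending, then credibility descending, then doc_id (a deterministic
  total order).
- Defaults `p = 0.95`, `K = 1000`. With `K = 10` ("depth-10 interpretation"),
  placing one helpful document in the top 10 yields help compatibility of
  roughly 0.1 on average over its ten possible positions (enumerated exactly
  in the tests) — the "one helpful document ≈ ten points" reading. The
  extreme placements fall outside a naive (0.03, 0.20) band: rank 1 alone is
  worth ≈ 0.33, rank 10 ≈ 0.008.
- Macro averages are unweighted means over topics, reported for three
  partitions: helpful-stance topics, unhelpful-stance topics, and all topics.
- A caveat inherited from the metric: promoting an ideal document above
  *another ideal document* can lower compatibility (it breaks their ideal
  relative order). The invariant that promotion never hurts holds only for
  promotion past non-ideal documents, and that is what the tests assert.

nDCG against the same polarity-graded documents is provided as a secondary
metric.

## Retrieval and preprocessing

- **BM25**: Okapi scoring with the non-negative IDF variant
  `ln((N − df + 0.5)/(df + 0.5) + 1)`; tokenization is lowercase `[a-z0-9]+`.
  Documents scoring 0 for a query are not retrieved. Defaults `k1 = 1.2`,
  `b = 0.75`. Parameters can be overridden per query without rebuilding the
  index (only the scoring formula changes, not the postings).
- **Known-item tuning**: without human judgments, "silver" topics are
  generated from sampled documents — query = top-5 TF-IDF keywords of the
  document, description = its first sentence (both generators pluggable, an
  identity-query generator is included). `(k1, b)` is grid-searched over
  `k1 ∈ {0.6, 0.9, 1.2, 1.5, 1.8} × b ∈ {0.3, 0.5, 0.75, 0.9}` maximizing the
  fraction of silver queries that retrieve their source document at rank 1;
  ties resolve to the first grid point in row-major order, so the result is
  deterministic.
- **Candidate selection** `H_P`: RRF fusion of the default-parameter and the
  tuned-parameter index's results, truncated to `n_docs` candidates
  (library default 10,000 per topic).

## Rank fusion

Reciprocal rank fusion scores each document `Σ_lists 1/(k + rank)` with
`k = 60` (the standard robust choice); ranks are 1-based and **all ties,
everywhere in the package, break by doc_id ascending**, which makes every
pipeline stage a deterministic function of its inputs. The weighted
alternative min-max normalizes each list's scores to [0, 1] (a constant list
maps to all 1s) and sums them with per-list weights; a weight-sweep utility
varies one weight over a grid with the others fixed.

## Quality dimensions

Neural models are replaced by **contracts**: a scorer exposes
`score(topic, doc) → float`, a claim checker `label(topic, doc) →
(label, confidence)` with labels supports/refutes/neutral. Any failure is
wrapped in an error naming the model and document.

- **Usefulness / credibility reranking**: each scorer in the ensemble sorts
  the candidates by its scores; the sorted lists are fused by RRF.
- **Supportiveness reranking**: the checker labels the top-k (k = 10)
  candidates; a majority vote among non-neutral labels decides the topic's
  claim stance (ties → undecided → ranking unchanged). The candidate list is
  then partitioned into stance-correct / neutral / stance-incorrect tiers,
  order-preserving within tiers. Multiple checkers are fused by RRF of their
  tiered rankings.
- **Credibility features** (for training real classifiers): SMOG readability
  `3.1291 + 1.0430·√(polysyllables · 30 / sentences)` (syllables = vowel
  groups, polysyllabic = ≥ 3), CSS design effort (style-block rules + inline
  styles + linked stylesheets, lxml with a regex fallback), and an importance
  proxy. The harness trains a random-forest classifier (100 trees, seeded).
  The final credibility score is the classifier's probability plus a unit
  bonus for documents from a curated trusted-domain list (suffix match on the
  registrable domain), so trusted pages always outrank untrusted ones; the
  score lives in [0, 2].

Each dimension ranking is `H_X = RRF(H_P, X′(H_P))` — anchoring to `H_P`
damps reranker mistakes. Combinations (`H_U+H_S`, `H_U+H_S+H_C`) fuse the
dimension rankings by RRF (default) or the weighted combination. No stage
introduces documents outside the candidate set. A depth-restricted variant
reranks only the top-n of a base ranking (fusing the reranked prefixes with
the base prefix, suffix untouched) to study how deep quality models must look.

## Synthetic benchmark and mock models

The generator plants ground truth in a vocabulary-based corpus
(`BenchmarkSpec`; defaults: 32 topics, 14 helpful / 18 unhelpful, 200
docs/topic, vocabulary 2000):

- each topic owns signature tokens; its query is three of them;
- useful documents (probability 0.2; grade 2 with probability 0.3 among them)
  contain 4–6 signature tokens, filler, and three stance-marker tokens;
  non-useful documents still contain one signature token, so BM25 retrieves
  topical-but-useless pages — giving usefulness models real headroom;
- stances are biased by topic polarity (75% supportive among non-neutral
  docs on helpful topics, 50% on unhelpful; 20% neutral), credibility is a
  coin flip (p = 0.5); preference labels follow the label rules above.

Mock scorers are deterministic: two uniforms are derived by hashing
`seed|dimension|fidelity|topic_id|doc_id` (BLAKE2b); with probability φ
(**fidelity**) the model returns the planted truth, otherwise uniform noise.
φ = 1 is an oracle, φ = 0 carries no signal (verified by chi-squared
independence tests), and help-harm compatibility is empirically monotone in φ
— the package's end-to-end acceptance property.

What the benchmark does **not** emulate: natural language (documents are
token bags), web-scale collections, correlated assessor noise, document
duplication, and any semantics of real medical claims. It exists to give the
pipeline a planted signal whose recovery can be asserted, not to predict
real-world effect sizes.

## Numerical and design choices

- All tie-breaks are lexicographic by doc_id; run files store scores with six
  decimals and round-trip byte-stably (ranks are re-derived from scores).
- RBO is computed incrementally with prefix-membership sets — O(K) per pair —
  and matches a brute-force term-by-term oracle to 1e−12 over an exhaustive
  enumeration of small rankings.
- Problem sizes in tests and the acceptance script (e.g. 1000 candidates per
  topic instead of 10,000, a fixed tuned-parameter pair in the end-to-end
  sweep) are the package's own desk-scale choices, made once for runtime
  budget reasons and not tuned against outcomes.
- Everything is deterministic given the seeds: benchmark generation, mock
  models, tuning, fusion and evaluation; repeated runs produce byte-identical
  run files.

## Limitations

- Compatibility is sensitive to the ideal's internal order (see the caveat
  above); conclusions should rely on macro averages, not single topics.
- The mock-model fidelity knob conflates all error modes into uniform noise;
  real quality models have structured errors (e.g. stance confusion on
  negated claims) that the contracts admit but the mocks do not simulate.
- SMOG's syllable counter is a vowel-group heuristic (English-only, no
  exception dictionary); the credibility harness is a scaffold, not a trained
  production model.
- The supportiveness vote assumes the retrieved majority reflects evidence;
  when a corpus is dominated by misinformation the tiering can invert, which
  the generator can simulate by flipping the stance biases.
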