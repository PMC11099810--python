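# qualrank

Quality-centred ranking for consumer health search.

People searching the web for health advice ("does treatment X help condition
Y?") are harmed not by irrelevant results but by *confident, on-topic
misinformation*. Plain lexical relevance ranking (BM25) happily surfaces a
well-written page recommending an ineffective treatment. `qualrank`
re-implements a multidimensional quality pipeline for this setting: retrieve
candidates lexically, then rerank them along three judged quality dimensions —
**usefulness** (topical pertinence), **supportiveness** (stance toward the
treatment claim) and **credibility** (trustworthiness of the source) — and
fuse the dimension rankings. Evaluation is by *compatibility*, a top-weighted
comparison of the system ranking against ideal rankings of helpful and of
harmful documents.

## The model in brief

**Compatibility.** For a system ranking `R` and an ideal ranking `I`,
truncated rank-biased overlap is

    RBO(R, I) = (1 − p) · Σ_{d=1..K} p^(d−1) · |R:d ∩ I:d| / d

with patience `p = 0.95` and evaluation depth `K = 1000` by default; `R:d` is
the depth-`d` prefix. Compatibility normalizes by the self-overlap of the
(finite) ideal: `C(R, I) = RBO(R, I) / RBO(I, I)`. **Help** compatibility uses
the ideal ranking of helpful documents, **harm** compatibility the ideal of
harmful ones, and the headline metric is `help − harm`: positive means the
ranking surfaces more helpful than harmful content early. With `K = 10`, one
helpful document in the top 10 is worth roughly ten points of help
compatibility.

**Pipeline.** `H_P` fuses a default and a known-item-tuned BM25 index by
reciprocal rank fusion (RRF, score `Σ 1/(60 + rank)`). Each quality dimension
produces `H_X = RRF(H_P, X′(H_P))` where `X′` reranks the candidates:
usefulness and credibility by score ensembles, supportiveness by a
majority-vote stance decision followed by three-tier reranking (stance-correct
documents first, neutral, then stance-incorrect, each tier order-preserving).
Combinations such as `H_U+H_S+H_C` fuse dimension rankings by RRF or a
weighted linear combination.

Neural quality models are out of scope; the package defines scorer/claim-checker
*contracts* and ships deterministic mock models whose **fidelity** φ ∈ [0, 1]
interpolates between ground truth (φ=1) and pure noise (φ=0), backed by a
planted synthetic benchmark generator.

## Worked example

```python
from qualrank import (Judgment, JudgmentSet, Ranking, Topic, compatibility,
                      derive_preference_labels, ideal_ranking)

topics = [Topic("t1", "honey cough children", stance="helpful")]
js = JudgmentSet()
js.add(Judgment("t1", "d_good1", usefulness=2, supportiveness="supportive", credibility=1))
js.add(Judgment("t1", "d_good2", usefulness=1, supportiveness="supportive", credibility=0))
js.add(Judgment("t1", "d_bad", usefulness=2, supportiveness="dissuasive", credibility=0))
qrels = derive_preference_labels(js, topics)

run = Ranking("t1", [("d_good1", 3.0), ("d_bad", 2.0), ("d_good2", 1.0)])
print(compatibility(run, ideal_ranking(qrels, "t1", "helpful")))  # 0.910...
print(compatibility(run, ideal_ranking(qrels, "t1", "harmful")))  # 0.683...
```

Running `python examples/evaluate_compatibility.py` prints:

```
ideal helpful ranking: ['d_good1', 'd_good2']
ideal harmful ranking: ['d_bad']
help compatibility  = 0.910  (how early the helpful docs appear)
harm compatibility  = 0.683  (how early the harmful doc appears)
help - harm         = 0.228  (positive: net helpful ranking)
```

The other scripts in `examples/` walk through BM25 known-item tuning, stance
tiering, credibility features, and a full synthetic-benchmark pipeline run.

## Command line

The `qualrank` CLI is a thin layer over the library:

```sh
qualrank simulate --seed 1 --out bench/            # planted benchmark
qualrank search --corpus bench/corpus.jsonl --topics bench/topics.json \
    --out run.txt                                  # BM25, TREC run format
qualrank evaluate --run run.txt --qrels bench/qrels.txt \
    --topics bench/topics.json --depth10           # help/harm compatibility
qualrank pipeline --benchmark bench/ --fidelity 1.0 --out runs/
```

See `qualrank --help` for `tune-bm25`, `rerank`, `fuse`, `depth-experiment`
and `weight-sweep`.

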