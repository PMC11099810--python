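"""End-to-end run on a planted synthetic benchmark.

The generator plants ground truth (usefulness grades, document stances,
credibility) in a vocabulary-based corpus; mock quality models read that
truth with a controllable fidelity. At fidelity 1 the pipeline shows the
headline effect: quality-aware reranking raises help-harm compatibility
over the BM25 baseline.
"""

from qualrank import (
    BenchmarkSpec,
    MockScorerSpec,
    PipelineConfig,
    generate_benchmark,
    mock_scorer,
    run_pipeline,
)

spec = BenchmarkSpec(n_topics=8, docs_per_topic=150, seed=4)
topics, corpus, qrels = generate_benchmark(spec)
print(f"benchmark: {len(topics)} topics "
      f"({sum(t.stance == 'helpful' for t in topics)} helpful), {len(corpus)} docs")

for fidelity in (0.0, 1.0):
    def mocks(dim):
        return [mock_scorer(MockScorerSpec(dim, fidelity, seed=0), qrels)]

    config = PipelineConfig(
        topics=topics, corpus=corpus, judgment_set=qrels,
        n_docs=300, tuned_params=(0.9, 0.5),
        usefulness_scorers=mocks("usefulness"),
        supportiveness_checkers=mocks("supportiveness"),
        credibility_scorers=mocks("credibility"),
    )
    result = run_pipeline(config)
    print(f"\nmock-model fidelity = {fidelity}")
    print("model            help   harm   help-harm")
    for name in ("H_P", "H_U", "H_S", "H_C", "H_U+H_S", "H_U+H_S+H_C"):
        row = result.reports[name].summary()["all_T"]
        print(f"{name:<15} {row['help']:6.3f} {row['harm']:6.3f} {row['help_harm']:8.3f}")

print("\nAt fidelity 1 the stance-aware models (H_S and the combinations) widen the")
print("help-harm margin over H_P; at fidelity 0 the models are noise and no run")
print("improves on the baseline. On a single tiny benchmark individual dimensions")
print("can fluctuate; the effect is stable when averaged over seeds.")
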