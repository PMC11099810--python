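"""End-to-end orchestration: candidate selection, per-dimension reranking,
combination, and evaluation.

The pipeline mirrors a two-phase quality-centred search system.  The
*preprocessing* phase retrieves N_D candidates per topic by fusing a
default-parameter and a known-item-tuned BM25 index (H_P).  The
*multidimensional ranking* phase reranks those candidates in parallel for
usefulness (H_U', an ensemble of similarity scorers fused by RRF),
supportiveness (H_S', stance-tiered claim checking) and credibility (H_C');
each dimension ranking H_X is the RRF combination of H_P with its reranked
list, and model combinations (H_U + H_S, H_U + H_S + H_C) fuse the dimension
rankings by RRF or by a weighted linear combination.  All stages only permute
(or truncate) the candidate set — no stage introduces unseen documents — and
every run is deterministic under the configured seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .benchmark_io import Document, JudgmentSet, Ranking, Topic
from .compatibility_eval import (
    CompatibilityParams,
    CompatibilityReport,
    help_harm_report,
)
from .lexical_retrieval import (
    DEFAULT_B,
    DEFAULT_B_GRID,
    DEFAULT_K1,
    DEFAULT_K1_GRID,
    DEFAULT_N_DOCS,
    build_index,
    generate_silver_topics,
    preprocess,
    tune_known_item,
)
from .rank_fusion import DEFAULT_RRF_K, depth_restricted_rerank, ensemble_rerank, rrf, weighted_combine
from .stance_reranker import DEFAULT_VOTE_K, supportiveness_rerank

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS = (10, 20, 50, 100, 1000)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline on one benchmark."""

    topics: Sequence[Topic]
    corpus: Mapping[str, Document]
    judgment_set: JudgmentSet | None = None

    # preprocessing
    n_docs: int = DEFAULT_N_DOCS
    rrf_k: float = DEFAULT_RRF_K
    default_params: tuple[float, float] = (DEFAULT_K1, DEFAULT_B)
    #: (k1, b) for the tuned index; None triggers known-item grid search
    tuned_params: tuple[float, float] | None = None
    k1_grid: Sequence[float] = DEFAULT_K1_GRID
    b_grid: Sequence[float] = DEFAULT_B_GRID
    n_silver_topics: int = 50

    # per-dimension models (empty list disables the dimension)
    usefulness_scorers: Sequence = ()
    supportiveness_checkers: Sequence = ()
    credibility_scorers: Sequence = ()
    stance_vote_k: int = DEFAULT_VOTE_K

    #: "rrf" fuses dimension rankings with RRF; "weighted" combines them
    #: linearly with ``weights`` (one per fused ranking).
    combination: str = "rrf"
    weights: Sequence[float] = ()

    eval_params: CompatibilityParams = field(default_factory=CompatibilityParams)
    seed: int = 0


@dataclass
class PipelineResult:
    """Named runs (each a per-topic list of rankings), their evaluation
    reports, and the BM25 parameters used."""

    runs: dict[str, list[Ranking]]
    reports: dict[str, CompatibilityReport]
    tuned_params: tuple[float, float]
    known_item_success: float | None = None


def run_dimension(h_p: Ranking, reranker: Callable[[Ranking], Ranking], rrf_k: float = DEFAULT_RRF_K) -> Ranking:
    """Combine the candidate ranking with one dimension's reranked list:
    H_X = RRF([H_P, reranker(H_P)]); covers exactly H_P's document set."""
    reranked = reranker(h_p)
    if set(reranked.doc_ids) != set(h_p.doc_ids):
        raise ValueError("reranker changed the candidate document set")
    return rrf([h_p, reranked], rrf_k=rrf_k)


def _combine(rankings: Sequence[Ranking], config: PipelineConfig) -> Ranking:
    if config.combination == "weighted":
        weights = list(config.weights) or [1.0] * len(rankings)
        return weighted_combine(rankings, weights[: len(rankings)])
    return rrf(rankings, rrf_k=config.rrf_k)


def _log_stage(stage: str, topic_id: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info(
        "stage=%s topic=%s in=%d out=%d elapsed=%.3fs",
        stage, topic_id, n_in, n_out, time.perf_counter() - t0,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run preprocessing, per-dimension reranking and combinations.

    Emits runs named H_P and, for each configured dimension, H_U / H_S / H_C
    plus the prime (reranking-only) runs H_U' / H_S' / H_C', and the
    combinations H_U+H_S and H_U+H_S+H_C when the needed dimensions exist.
    Evaluation reports are produced when a judgment set is configured.
    """
    t0 = time.perf_counter()
    k1_d, b_d = config.default_params
    index_default = build_index(config.corpus, k1=k1_d, b=b_d)
    success: float | None = None
    if config.tuned_params is None:
        silver = generate_silver_topics(
            config.corpus, n=config.n_silver_topics, seed=config.seed
        )
        k1_t, b_t, success = tune_known_item(
            config.corpus, silver, k1_grid=config.k1_grid, b_grid=config.b_grid
        )
        logger.info("known-item tuning: k1=%s b=%s success=%.3f", k1_t, b_t, success)
    else:
        k1_t, b_t = config.tuned_params
    index_tuned = build_index(config.corpus, k1=k1_t, b=b_t)
    logger.info("indices built over %d docs in %.2fs", len(config.corpus), time.perf_counter() - t0)

    runs: dict[str, list[Ranking]] = {"H_P": []}
    dims: dict[str, list[Ranking]] = {}
    primes: dict[str, list[Ranking]] = {}

    use_u = bool(config.usefulness_scorers)
    use_s = bool(config.supportiveness_checkers)
    use_c = bool(config.credibility_scorers)

    for topic in config.topics:
        ts = time.perf_counter()
        try:
            h_p = preprocess(
                topic, index_default, index_tuned,
                n_docs=config.n_docs, rrf_k=config.rrf_k,
            )
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess topic={topic.topic_id}: {exc}") from exc
        _log_stage("preprocess", topic.topic_id, len(config.corpus), len(h_p), ts)
        runs["H_P"].append(h_p)

        stage_outputs: dict[str, Ranking] = {}
        try:
            if use_u:
                h_u_prime = ensemble_rerank(
                    h_p, config.usefulness_scorers, topic, config.corpus,
                    rrf_k=config.rrf_k,
                )
                primes.setdefault("H_U'", []).append(h_u_prime)
                stage_outputs["H_U"] = rrf([h_p, h_u_prime], rrf_k=config.rrf_k)
            if use_s:
                h_s_prime = supportiveness_rerank(
                    topic, h_p, config.supportiveness_checkers, config.corpus,
                    k=config.stance_vote_k, rrf_k=config.rrf_k,
                )
                primes.setdefault("H_S'", []).append(h_s_prime)
                stage_outputs["H_S"] = rrf([h_p, h_s_prime], rrf_k=config.rrf_k)
            if use_c:
                h_c_prime = ensemble_rerank(
                    h_p, config.credibility_scorers, topic, config.corpus,
                    rrf_k=config.rrf_k,
                )
                primes.setdefault("H_C'", []).append(h_c_prime)
                stage_outputs["H_C"] = rrf([h_p, h_c_prime], rrf_k=config.rrf_k)
        except Exception as exc:
            raise RuntimeError(f"stage=rerank topic={topic.topic_id}: {exc}") from exc
        for name, ranking in stage_outputs.items():
            dims.setdefault(name, []).append(ranking)
        _log_stage("rerank", topic.topic_id, len(h_p), len(h_p), ts)

        try:
            if use_u and use_s:
                combo = _combine([stage_outputs["H_U"], stage_outputs["H_S"]], config)
                dims.setdefault("H_U+H_S", []).append(combo)
            if use_u and use_s and use_c:
                combo = _combine(
                    [stage_outputs["H_U"], stage_outputs["H_S"], stage_outputs["H_C"]],
                    config,
                )
                dims.setdefault("H_U+H_S+H_C", []).append(combo)
        except Exception as exc:
            raise RuntimeError(f"stage=combine topic={topic.topic_id}: {exc}") from exc

    runs.update(primes)
    runs.update(dims)

    reports: dict[str, CompatibilityReport] = {}
    if config.judgment_set is not None:
        for name, rankings in runs.items():
            reports[name] = help_harm_report(
                rankings, config.judgment_set, config.topics, params=config.eval_params
            )
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return PipelineResult(
        runs=runs, reports=reports, tuned_params=(k1_t, b_t), known_item_success=success
    )


def run_depth_experiment(
    config: PipelineConfig,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    result: PipelineResult | None = None,
) -> dict[int, CompatibilityReport]:
    """Depth-restricted reranking curves.

    Takes the usefulness ranking H_U as the base and reranks only its top-n
    documents with the supportiveness and credibility rerankers (fused with
    the base prefix via RRF), for each depth; evaluates each resulting run.
    """
    if result is None:
        result = run_pipeline(config)
    if "H_U" not in result.runs:
        raise ValueError("depth experiment needs a usefulness dimension (H_U)")
    if config.judgment_set is None:
        raise ValueError("depth experiment needs a judgment set to evaluate")
    topics_by_id = {t.topic_id: t for t in config.topics}
    curves: dict[int, CompatibilityReport] = {}
    for depth in depths:
        rankings = []
        for base in result.runs["H_U"]:
            topic = topics_by_id[base.topic_id]
            rerankers: list[Callable[[Ranking], Ranking]] = []
            if config.supportiveness_checkers:
                rerankers.append(
                    lambda prefix, t=topic: supportiveness_rerank(
                        t, prefix, config.supportiveness_checkers, config.corpus,
                        k=config.stance_vote_k, rrf_k=config.rrf_k,
                    )
                )
            if config.credibility_scorers:
                rerankers.append(
                    lambda prefix, t=topic: ensemble_rerank(
                        prefix, config.credibility_scorers, t, config.corpus,
                        rrf_k=config.rrf_k,
                    )
                )
            rankings.append(
                depth_restricted_rerank(base, rerankers, depth, rrf_k=config.rrf_k)
            )
        curves[depth] = help_harm_report(
            rankings, config.judgment_set, config.topics, params=config.eval_params
        )
    return curves
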