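"""Credibility dimension: readability, page-design and link features, a random
forest harness over 1–5 credibility ratings, a trusted-domain bonus, and the
credibility reranking step.

Features follow the classic web-credibility literature: the SMOG readability
index (years of education needed to understand the text), the number of CSS
style definitions as a proxy for page-design effort, and a page-rank value
from a pluggable provider (no network access; a file of URL → score works).
A random forest is trained on pages rated 1 ("very noncredible") to 5 ("very
credible"), binarized so that ratings 4–5 mean credible.  The final score of
a document is the classifier's credible-class probability plus a unit bonus
when the document's URL belongs to a trusted-domain list (e.g. sites vetted
by a health-certification registry), so trusted documents always outrank
untrusted ones.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence
from urllib.parse import urlparse

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .benchmark_io import Document, Ranking

#: SMOG grade for a text with no polysyllabic words (formula floor).
SMOG_FLOOR = 3.1291

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_WORD_RE = re.compile(r"[a-zA-Z]+")
_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Syllables approximated as maximal vowel groups (a/e/i/o/u/y)."""
    return len(_VOWEL_GROUP.findall(word.lower()))


def smog_index(
    text: str, syllable_counter: Callable[[str], int] = count_syllables
) -> float:
    """SMOG readability: 3.1291 + 1.0430 * sqrt(polysyllables * 30 / sentences).

    Sentences split on terminal punctuation (.!?); words are alphabetic
    tokens; a polysyllabic word has >= 3 syllables.  Invariant under text
    duplication (the polysyllable/sentence ratio is unchanged).
    """
    if not text or not text.strip():
        raise ValueError("empty text")
    sentences = [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]
    n_sentences = max(len(sentences), 1)
    polysyllables = sum(
        1 for w in _WORD_RE.findall(text) if syllable_counter(w) >= 3
    )
    return SMOG_FLOOR + 1.0430 * math.sqrt(polysyllables * 30.0 / n_sentences)


_STYLE_BLOCK = re.compile(r"<style[^>]*>(.*?)</style>", re.IGNORECASE | re.DOTALL)
_INLINE_STYLE = re.compile(r"""\sstyle\s*=\s*("[^"]*"|'[^']*')""", re.IGNORECASE)
_LINK_SHEET = re.compile(
    r"""<link[^>]*rel\s*=\s*["']?stylesheet["']?[^>]*>""", re.IGNORECASE
)


def count_css_rules(html: str) -> int:
    """Best-effort count of CSS style definitions in an HTML string.

    Counts rule blocks (``{...}``) inside ``<style>`` elements, plus inline
    ``style=`` attributes, plus linked stylesheets (one each).  Malformed
    HTML is handled by falling back to regular-expression scanning; plain
    text scores 0.
    """
    if not html:
        return 0
    try:
        import lxml.html

        root = lxml.html.fromstring(html)
        n = 0
        for style in root.iter("style"):
            n += (style.text or "").count("{")
        n += len(root.xpath("//*[@style]"))
        n += len(
            [
                el
                for el in root.iter("link")
                if (el.get("rel") or "").lower() == "stylesheet"
            ]
        )
        return n
    except Exception:
        n = sum(block.count("{") for block in _STYLE_BLOCK.findall(html))
        n += len(_INLINE_STYLE.findall(html))
        n += len(_LINK_SHEET.findall(html))
        return n


def count_stylesheet_files(html: str) -> int:
    """Alternative count: linked stylesheet files plus embedded <style> blocks."""
    if not html:
        return 0
    return len(_LINK_SHEET.findall(html)) + len(_STYLE_BLOCK.findall(html))


@dataclass(frozen=True)
class CredibilityFeatures:
    """Feature vector for the credibility classifier."""

    smog: float
    css_rule_count: int
    page_rank: float = 0.0
    extra: Mapping[str, float] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        extras = [self.extra[k] for k in sorted(self.extra)]
        return np.array(
            [self.smog, float(self.css_rule_count), self.page_rank, *extras],
            dtype=np.float64,
        )


def extract_features(
    doc: Document, page_rank_provider: Mapping[str, float] | None = None
) -> CredibilityFeatures:
    """Compute credibility features for one document.

    ``page_rank_provider`` maps URLs (or registrable domains) to scores;
    unknown URLs score 0.
    """
    pr = 0.0
    if page_rank_provider and doc.url:
        pr = float(
            page_rank_provider.get(
                doc.url, page_rank_provider.get(registrable_domain(doc.url), 0.0)
            )
        )
    return CredibilityFeatures(
        smog=smog_index(doc.text),
        css_rule_count=count_css_rules(doc.html or ""),
        page_rank=pr,
    )


def binarize_credibility(score_1_to_5: int) -> int:
    """Map a 1–5 credibility rating to binary: 4 and 5 are credible (1)."""
    if not isinstance(score_1_to_5, (int, np.integer)) or not 1 <= score_1_to_5 <= 5:
        raise ValueError(f"credibility rating must be an integer in 1..5, got {score_1_to_5!r}")
    return 1 if score_1_to_5 >= 4 else 0


def train_credibility_classifier(
    features: Sequence[CredibilityFeatures],
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 100,
) -> RandomForestClassifier:
    """Fit a random forest on binarized credibility labels.

    Deterministic under ``seed``; both classes must be present.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("need both credible and noncredible examples to train")
    X = np.vstack([f.as_array() for f in features])
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return clf


class TrustedDomainList:
    """Set of trusted registrable domains, matched as URL-host suffixes."""

    def __init__(self, domains: Iterable[str] = ()):
        self.domains = {d.strip().lower() for d in domains if d.strip()}

    @classmethod
    def from_file(cls, path) -> "TrustedDomainList":
        with open(path, encoding="utf-8") as fh:
            return cls(line for line in fh)

    def matches(self, url: str) -> bool:
        if not url:
            return False
        host = registrable_domain(url, full_host=True)
        return any(
            host == d or host.endswith("." + d) for d in self.domains
        )


def registrable_domain(url: str, full_host: bool = False) -> str:
    """Lower-cased host of a URL; with ``full_host=False``, its last two labels."""
    host = urlparse(url if "//" in url else "//" + url).hostname or ""
    host = host.lower()
    if full_host:
        return host
    parts = host.split(".")
    return ".".join(parts[-2:]) if len(parts) >= 2 else host


def credibility_score(
    doc: Document,
    classifier: RandomForestClassifier,
    trusted: TrustedDomainList | None = None,
    page_rank_provider: Mapping[str, float] | None = None,
) -> float:
    """Credible-class probability plus 1.0 if the URL is trusted; in [0, 2].

    The unit bonus strictly dominates the probability term, so any trusted
    document outranks every untrusted one.
    """
    feats = extract_features(doc, page_rank_provider=page_rank_provider)
    proba = float(classifier.predict_proba(feats.as_array().reshape(1, -1))[0, 1])
    bonus = 1.0 if (trusted is not None and trusted.matches(doc.url)) else 0.0
    return proba + bonus


def credibility_rerank(base: Ranking, scores: Mapping[str, float]) -> Ranking:
    """Permute base by credibility score descending, doc_id ascending."""
    missing = [d for d in base.doc_ids if d not in scores]
    if missing:
        raise ValueError(f"missing credibility scores for: {missing[:5]}")
    return Ranking.from_scores(
        base.topic_id, {d: float(scores[d]) for d in base.doc_ids}, run_tag=base.run_tag
    )
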