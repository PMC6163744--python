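"""Tokenization, bag-of-words corpora and tf-idf vocabulary selection.

Tokens are lowercased Unicode word sequences of length >= 2 with accents
preserved; URLs and user handles are stripped beforehand (low-engagement
group text is often dominated by spam artifacts carrying both).  A
configurable stopword list removes function words; a default Spanish list
ships with the package.

tf-idf is computed over exactly three "documents" — the concatenated
low/medium/high engagement groups — so a term occurring at every
engagement level gets idf 0 and drops out of every group's vocabulary.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

GROUPS = ("low", "medium", "high")

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_HANDLE_RE = re.compile(r"@\w+", re.UNICODE)
_WORD_RE = re.compile(r"[^\W\d_]{2,}", re.UNICODE)


@dataclass(frozen=True)
class TokenConfig:
    """Tokenizer settings.

    ``min_length`` is the minimum token length in characters; ``stopwords``
    is the active stopword set (empty set disables filtering); URLs and
    @handles are removed before word extraction when the flags are set.
    """

    min_length: int = 2
    stopwords: frozenset[str] = frozenset()
    strip_urls: bool = True
    strip_handles: bool = True


def load_stopwords(path=None) -> frozenset[str]:
    """Load a stopword list (one lowercase term per line, UTF-8).

    With no path, returns the bundled Spanish list.
    """
    if path is None:
        text = (
            resources.files("postmine.data").joinpath("stopwords_es.txt").read_text("utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(
        line.strip().lower() for line in text.splitlines() if line.strip()
    )


def default_token_config() -> TokenConfig:
    """Token config with the bundled Spanish stopword list active."""
    return TokenConfig(stopwords=load_stopwords())


def tokenize(text: str, config: TokenConfig = TokenConfig()) -> list[str]:
    """Split text into lowercase word tokens.

    Digits and punctuation never appear in tokens; accented letters do.
    """
    if config.strip_urls:
        text = _URL_RE.sub(" ", text)
    if config.strip_handles:
        text = _HANDLE_RE.sub(" ", text)
    tokens = [m.group(0).lower() for m in _WORD_RE.finditer(text)]
    return [
        t
        for t in tokens
        if len(t) >= config.min_length and t not in config.stopwords
    ]


@dataclass(frozen=True)
class Corpus:
    """Bag-of-words term counts plus the total token count.

    ``total_tokens`` is always the sum of ``term_counts`` values — it is
    the marginal total (the *c* or *d*) a contingency row uses.
    """

    term_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def total_tokens(self) -> int:
        return sum(self.term_counts.values())

    def __contains__(self, term: str) -> bool:
        return term in self.term_counts

    def count(self, term: str) -> int:
        return self.term_counts.get(term, 0)


def build_corpus(texts: Iterable[str], config: TokenConfig = TokenConfig()) -> Corpus:
    """Aggregate token counts over a collection of texts."""
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(tokenize(text, config))
    return Corpus(term_counts=dict(counts))


@dataclass(frozen=True)
class TfidfTable:
    """Per-group term weights; group keys are ``low``, ``medium``, ``high``."""

    weights: Mapping[str, Mapping[str, float]]

    def group(self, name: str) -> Mapping[str, float]:
        return self.weights[name]


def tfidf_by_group(group_corpora: Mapping[str, Corpus]) -> TfidfTable:
    """tf-idf with the three engagement groups as the document set.

    tf(term, g) = count / total tokens of g (0 for an empty group);
    idf(term) = ln(3 / number of groups containing term), natural log.
    A term present at all three engagement levels therefore weighs
    exactly 0 everywhere — ubiquitous vocabulary is discarded.
    """
    missing = set(GROUPS) - set(group_corpora)
    if missing:
        raise ValueError(f"missing engagement groups: {sorted(missing)}")
    df: Counter[str] = Counter()
    for g in GROUPS:
        for term in group_corpora[g].term_counts:
            df[term] += 1
    weights: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        corpus = group_corpora[g]
        total = corpus.total_tokens
        gw: dict[str, float] = {}
        for term, count in corpus.term_counts.items():
            tf = count / total if total else 0.0
            idf = math.log(len(GROUPS) / df[term])
            gw[term] = tf * idf
        weights[g] = gw
    return TfidfTable(weights=weights)


def top_terms(weights: Mapping[str, float] | Corpus, k: int) -> list[tuple[str, float]]:
    """The k highest-weighted terms, descending, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(weights, Corpus):
        weights = weights.term_counts
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(t, float(w)) for t, w in ranked[:k]]
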