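"""Lexicon-based polarity and subjectivity scoring.

A transparent bag-of-words scorer: each lexicon term carries a polarity
weight in [-1, 1] and a subjectivity weight in [0, 1]; the score of a
text is the mean over matched terms, after applying negation and
intensification.  A negator within the 3 tokens preceding a match flips
and damps its polarity (factor -0.5, the usual "not good" != "bad"
asymmetry); an intensifier multiplies it by its own factor.  Final means
are clamped to the declared ranges; a text with no matches scores (0, 0).

The bundled lexicon is small and bilingual (Spanish plus English) —
enough to drive the pipeline and its tests; real analyses should supply
a domain lexicon via :func:`load_lexicon`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .corpus_io import Post
from .text_prep import TokenConfig, tokenize

NEGATION_WINDOW = 3
NEGATION_FACTOR = -0.5

# sentiment keeps stopwords: negators ("no", "not") are function words
_SENTIMENT_TOKENS = TokenConfig(min_length=2, stopwords=frozenset())


@dataclass(frozen=True)
class SentimentLexicon:
    """Term weights plus negator and intensifier word lists."""

    entries: Mapping[str, tuple[float, float]]  # term -> (polarity, subjectivity)
    negators: frozenset[str] = frozenset()
    intensifiers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (pol, subj) in self.entries.items():
            if not -1.0 <= pol <= 1.0:
                raise ValueError(f"{term!r}: polarity {pol} outside [-1, 1]")
            if not 0.0 <= subj <= 1.0:
                raise ValueError(f"{term!r}: subjectivity {subj} outside [0, 1]")
        for term, factor in self.intensifiers.items():
            if factor <= 0:
                raise ValueError(f"intensifier {term!r} needs a positive factor")


@dataclass(frozen=True)
class SentimentScore:
    """Polarity in [-1, 1], subjectivity in [0, 1], and the match count."""

    polarity: float
    subjectivity: float
    matched_terms: int


def load_lexicon(path=None) -> SentimentLexicon:
    """Load a lexicon CSV: term, polarity, subjectivity, role, factor.

    ``role`` is one of ``term`` (default), ``negator``, ``intensifier``;
    ``factor`` is the intensifier multiplier.  With no path, the bundled
    bilingual lexicon is returned.
    """
    if path is None:
        text = resources.files("postmine.data").joinpath("lexicon.csv").read_text("utf-8")
        lines = text.splitlines()
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    entries: dict[str, tuple[float, float]] = {}
    negators: set[str] = set()
    intensifiers: dict[str, float] = {}
    for row in csv.DictReader(lines):
        term = row["term"].strip().lower()
        role = (row.get("role") or "term").strip().lower()
        if role == "negator":
            negators.add(term)
        elif role == "intensifier":
            intensifiers[term] = float(row["factor"])
        else:
            entries[term] = (float(row["polarity"]), float(row["subjectivity"]))
    return SentimentLexicon(
        entries=entries, negators=frozenset(negators), intensifiers=intensifiers
    )


def _clamp(value: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, value))


def score(text: str, lexicon: SentimentLexicon) -> SentimentScore:
    """Score one text against a lexicon.

    Deterministic; tokenization keeps stopwords so negators are seen.
    """
    tokens = tokenize(text, _SENTIMENT_TOKENS)
    polarities: list[float] = []
    subjectivities: list[float] = []
    for i, token in enumerate(tokens):
        if token not in lexicon.entries:
            continue
        pol, subj = lexicon.entries[token]
        window = tokens[max(0, i - NEGATION_WINDOW) : i]
        for prev in window:
            if prev in lexicon.negators:
                pol *= NEGATION_FACTOR
            elif prev in lexicon.intensifiers:
                pol *= lexicon.intensifiers[prev]
        polarities.append(pol)
        subjectivities.append(subj)
    if not polarities:
        return SentimentScore(0.0, 0.0, 0)
    return SentimentScore(
        polarity=_clamp(sum(polarities) / len(polarities), -1.0, 1.0),
        subjectivity=_clamp(sum(subjectivities) / len(subjectivities), 0.0, 1.0),
        matched_terms=len(polarities),
    )


def score_posts(
    posts: Iterable[Post], lexicon: SentimentLexicon
) -> dict[str, SentimentScore]:
    """Score every post's message; keyed by post_id."""
    return {p.post_id: score(p.message, lexicon) for p in posts}
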