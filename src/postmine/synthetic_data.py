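"""Synthetic post corpora and reference documents for pipeline testing.

Real group exports from the platform cannot be redistributed, so every
pipeline stage is exercised against generated data with the same
statistical structure:

* six post types drawn from a multinomial whose default probabilities
  match the observed type mix of a rare-disease group corpus
  (status and link posts dominate; notes and events are rare);
* per-type interaction counts from an overdispersed (negative-binomial)
  model — count variance in such data always exceeds the mean — with
  reactions = likes + extra reactions, so reactions >= likes holds by
  construction;
* a bimodal diurnal posting rhythm peaking after lunch (13:00-15:00)
  and late evening (20:00-00:00), with the overnight trough at 06:00;
* bag-of-words messages over a topic vocabulary with planted
  corpus-enriched keywords (enrichment factor > 1 means the term is
  over-represented in the reference document, < 1 over-represented in
  the posts);
* sentiment words mixed in with an hour-dependent positive/negative
  balance, so mean polarity drifts across the day (morning highest,
  night lowest).

One integer seed drives a single numpy Generator; the per-post draw
order (type, timestamp, counts, message) is fixed, so outputs are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import yaml

from .corpus_io import DEFAULT_TIMEZONE, POST_TYPES, Post

#: Observed type mix: event, link, note, photo, status, video.
DEFAULT_TYPE_COUNTS = {
    "event": 34,
    "link": 1063,
    "note": 9,
    "photo": 792,
    "status": 1787,
    "video": 232,
}

#: Per-type (mean, std) of likes, comments, shares, plus the mean number
#: of non-like reactions (reaction means exceed like means only slightly).
DEFAULT_COUNT_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "event": {"likes": (3.8, 4.3), "comments": (0.3, 0.6), "shares": (4.1, 9.7), "extra_reactions": (0.1, 0.4)},
    "link": {"likes": (5.2, 6.1), "comments": (0.8, 1.9), "shares": (0.0, 0.4), "extra_reactions": (0.1, 0.4)},
    "note": {"likes": (2.3, 3.2), "comments": (0.4, 1.0), "shares": (0.0, 0.0), "extra_reactions": (0.0, 0.0)},
    "photo": {"likes": (12.0, 12.8), "comments": (2.6, 5.3), "shares": (0.9, 4.9), "extra_reactions": (0.2, 0.6)},
    "status": {"likes": (4.6, 6.5), "comments": (2.9, 5.9), "shares": (0.1, 1.4), "extra_reactions": (0.1, 0.4)},
    "video": {"likes": (6.1, 6.4), "comments": (0.8, 1.8), "shares": (0.4, 3.0), "extra_reactions": (0.0, 0.0)},
}

#: Diurnal posting intensity (relative weights per hour 0-23): peaks at
#: 13:00-15:00 and 20:00-00:00, trough at 06:00.
DEFAULT_HOURLY_INTENSITY = (
    0.8, 0.5, 0.3, 0.2, 0.2, 0.15,  # 0-5
    0.1, 0.3, 0.5, 0.8,             # 6-9
    1.0, 1.2, 1.4,                  # 10-12
    2.5, 2.5, 1.5,                  # 13-15
    1.2, 1.1, 1.3, 1.5,             # 16-19
    2.4, 2.5, 2.5, 2.3,             # 20-23
)

#: Topic vocabulary with base sampling weights (shared by both corpora).
DEFAULT_VOCABULARY: dict[str, float] = {
    "síndrome": 8.0, "enfermedad": 6.0, "enfermedades": 4.0, "niños": 5.0,
    "familia": 5.0, "asociación": 4.0, "tratamiento": 4.0, "médico": 3.5,
    "hospital": 3.0, "investigación": 3.0, "pacientes": 3.0, "personas": 4.0,
    "salud": 3.0, "atención": 2.5, "diagnóstico": 2.0, "terapia": 2.0,
    "grupo": 2.5, "información": 2.5, "proyecto": 1.5, "congreso": 1.0,
    "derechos": 1.5, "servicios": 1.5, "centro": 1.5, "escuela": 1.5,
    "ayuda": 5.0, "vida": 5.0, "hijo": 4.0, "discapacidad": 1.0,
    "nacional": 1.0, "profesionales": 1.0, "nivel": 1.0, "referencia": 1.0,
}

#: Enrichment factors: reference-document weight = base weight x factor.
#: > 1 plants a reference-enriched term, < 1 a post-corpus-enriched one.
DEFAULT_PLANTED_KEYWORDS: dict[str, float] = {
    "discapacidad": 8.0,
    "nacional": 6.0,
    "profesionales": 5.0,
    "ayuda": 0.1,
    "vida": 0.12,
    "hijo": 0.1,
}

#: Mean-polarity drift by hour: positive mornings, negative nights.
DEFAULT_SENTIMENT_DRIFT = tuple(
    {"morning": 0.35, "afternoon": 0.15, "evening": -0.1, "night": -0.35}[
        "morning" if 6 <= h < 12 else
        "afternoon" if 12 <= h < 18 else
        "evening" if 18 <= h < 24 else "night"
    ]
    for h in range(24)
)

POSITIVE_WORDS = ("gracias", "feliz", "alegría", "esperanza", "apoyo", "maravilloso")
NEGATIVE_WORDS = ("triste", "dolor", "miedo", "crisis", "difícil", "peor")


class GeneratorConfigError(ValueError):
    """The generator configuration violates an invariant."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic corpus.

    Defaults encode the study conditions described in the module
    docstring; tests and callers override only what they probe.
    """

    n_posts: int = 3917
    seed: int = 0
    type_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            t: c / sum(DEFAULT_TYPE_COUNTS.values())
            for t, c in DEFAULT_TYPE_COUNTS.items()
        }
    )
    count_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_COUNT_MODEL
    )
    hourly_intensity: Sequence[float] = DEFAULT_HOURLY_INTENSITY
    vocabulary: Mapping[str, float] = field(default_factory=lambda: DEFAULT_VOCABULARY)
    planted_keywords: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_PLANTED_KEYWORDS
    )
    sentiment_drift: Sequence[float] = DEFAULT_SENTIMENT_DRIFT
    mean_topic_words: float = 8.0
    mean_sentiment_words: float = 2.0
    start_date: date = date(2017, 1, 1)
    n_days: int = 540
    timezone: str = DEFAULT_TIMEZONE

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise GeneratorConfigError("n_posts must be >= 1")
        if set(self.type_probs) - set(POST_TYPES):
            raise GeneratorConfigError("type_probs has unknown post types")
        if abs(sum(self.type_probs.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("type_probs must sum to 1")
        if len(self.hourly_intensity) != 24:
            raise GeneratorConfigError("hourly_intensity needs 24 weights")
        if min(self.hourly_intensity) < 0 or sum(self.hourly_intensity) <= 0:
            raise GeneratorConfigError(
                "hourly_intensity must be non-negative with positive sum"
            )
        if len(self.sentiment_drift) != 24:
            raise GeneratorConfigError("sentiment_drift needs 24 offsets")
        if not self.vocabulary:
            raise GeneratorConfigError("vocabulary must be non-empty")
        if any(f <= 0 for f in self.planted_keywords.values()):
            raise GeneratorConfigError("enrichment factors must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "start_date" in raw and isinstance(raw["start_date"], str):
            raw["start_date"] = date.fromisoformat(raw["start_date"])
        return cls(**raw)


def _sample_count(rng: np.random.Generator, mean: float, std: float) -> int:
    """Negative binomial when overdispersed, Poisson otherwise."""
    if mean <= 0:
        return 0
    var = std * std
    if var > mean:
        r = mean * mean / (var - mean)
        return int(rng.negative_binomial(r, r / (r + mean)))
    return int(rng.poisson(mean))


def _reference_weights(config: GeneratorConfig) -> tuple[list[str], np.ndarray]:
    terms = sorted(config.vocabulary)
    w = np.array(
        [
            config.vocabulary[t] * config.planted_keywords.get(t, 1.0)
            for t in terms
        ]
    )
    return terms, w / w.sum()


def _post_weights(config: GeneratorConfig) -> tuple[list[str], np.ndarray]:
    terms = sorted(config.vocabulary)
    w = np.array([config.vocabulary[t] for t in terms])
    return terms, w / w.sum()


def generate_posts(config: GeneratorConfig = GeneratorConfig()) -> list[Post]:
    """Generate a deterministic post collection for a seeded config."""
    rng = np.random.default_rng(config.seed)
    tz = ZoneInfo(config.timezone)
    types = sorted(config.type_probs)
    type_p = np.array([config.type_probs[t] for t in types])
    hours = np.asarray(config.hourly_intensity, dtype=float)
    hour_p = hours / hours.sum()
    terms, term_p = _post_weights(config)
    posts: list[Post] = []
    for i in range(config.n_posts):
        post_type = types[rng.choice(len(types), p=type_p)]
        day = int(rng.integers(config.n_days))
        hour = int(rng.choice(24, p=hour_p))
        minute, second = int(rng.integers(60)), int(rng.integers(60))
        created = datetime.combine(
            config.start_date + timedelta(days=day),
            datetime.min.time(),
            tzinfo=tz,
        ) + timedelta(hours=hour, minutes=minute, seconds=second)
        model = config.count_model[post_type]
        likes = _sample_count(rng, *model["likes"])
        extra = _sample_count(rng, *model["extra_reactions"])
        comments = _sample_count(rng, *model["comments"])
        shares = _sample_count(rng, *model["shares"])
        n_topic = 2 + int(rng.poisson(config.mean_topic_words))
        words = [terms[j] for j in rng.choice(len(terms), size=n_topic, p=term_p)]
        n_sent = int(rng.poisson(config.mean_sentiment_words))
        p_pos = float(np.clip(0.5 + config.sentiment_drift[hour], 0.05, 0.95))
        for _ in range(n_sent):
            pool = POSITIVE_WORDS if rng.random() < p_pos else NEGATIVE_WORDS
            words.append(pool[rng.integers(len(pool))])
        rng.shuffle(words)
        posts.append(
            Post(
                post_id=f"p{i:06d}",
                post_type=post_type,
                message=" ".join(words),
                created=created,
                likes=likes,
                comments=comments,
                shares=shares,
                reactions=likes + extra,
            )
        )
    return posts


def generate_reference_document(
    config: GeneratorConfig = GeneratorConfig(), n_tokens: int = 1500
) -> str:
    """Generate the reference priority document (decalogue stand-in).

    Term relative frequencies follow the vocabulary weights multiplied
    by the planted enrichment factors; ten words per line.
    """
    rng = np.random.default_rng(config.seed + 1)
    terms, weights = _reference_weights(config)
    drawn = [terms[j] for j in rng.choice(len(terms), size=n_tokens, p=weights)]
    lines = [" ".join(drawn[i : i + 10]) for i in range(0, len(drawn), 10)]
    return "\n".join(lines) + "\n"
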