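"""Dataset characterization and end-to-end pipeline orchestration.

``run_pipeline`` chains the whole analysis — anonymize, characterize,
engagement tertiles, tf-idf vocabulary per tertile, keyness against the
reference document, sentiment, temporal aggregates, correlation grid —
and writes one CSV per stage plus a full-precision JSON summary.  The
pipeline is a pure function of its input files and config: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import association, corpus_compare, corpus_io, sentiment, temporal, text_prep
from .corpus_io import MaskingRules, Post, TableDialect
from .engagement import engagement, tertile_split

logger = logging.getLogger(__name__)

COUNT_ATTRS = ("likes", "comments", "reactions", "shares")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def characterize(posts: Sequence[Post]) -> pd.DataFrame:
    """Per-type mean (population std) of the interaction counts.

    One row per observed post type plus a ``total`` row; columns are the
    four counts, engagement and the instance count.  Instance counts sum
    to the number of posts.
    """
    if not posts:
        raise ValueError("characterize needs at least one post")
    records = [
        {
            "post_type": p.post_type,
            **{attr: getattr(p, attr) for attr in COUNT_ATTRS},
            "engagement": engagement(p),
        }
        for p in posts
    ]
    df = pd.DataFrame(records)
    metrics = [*COUNT_ATTRS, "engagement"]
    rows = []
    for ptype, sub in [*df.groupby("post_type", sort=True), ("total", df)]:
        row: dict[str, object] = {"post_type": ptype}
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_std"] = float(sub[m].std(ddof=0))
        row["instances"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one pipeline run."""

    posts_path: Path
    reference_path: Path
    output_dir: Path
    lexicon_path: Path | None = None  # None -> bundled lexicon
    stopwords_path: Path | None = None  # None -> bundled Spanish list
    dialect: TableDialect = field(default_factory=TableDialect)
    masking: MaskingRules = field(default_factory=MaskingRules)
    min_count: int = 1
    top_k_terms: int = 25
    lenient: bool = False


def _tertile_corpora(
    posts: Sequence[Post], assignment, config: text_prep.TokenConfig
) -> dict[str, text_prep.Corpus]:
    return {
        g: text_prep.build_corpus(
            [p.message for p in posts if assignment[p.post_id] == g], config
        )
        for g in text_prep.GROUPS
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns the map of output names to paths.

    Any stage error aborts with a :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        outputs[name] = path

    stage = "read_inputs"
    try:
        posts = corpus_io.read_posts(
            config.posts_path, config.dialect, lenient=config.lenient
        )
        reference_text = corpus_io.read_reference_document(config.reference_path)
        stopwords = text_prep.load_stopwords(config.stopwords_path)
        token_config = text_prep.TokenConfig(stopwords=stopwords)
        lexicon = sentiment.load_lexicon(config.lexicon_path)
        logger.info("read %d posts", len(posts))

        stage = "anonymize"
        posts = corpus_io.anonymize(posts, config.masking)

        stage = "characterize"
        write_csv("characterization", characterize(posts))

        stage = "tertiles"
        tertiles = tertile_split(posts)
        write_csv(
            "tertiles",
            pd.DataFrame(
                {
                    "post_id": [p.post_id for p in posts],
                    "engagement": [engagement(p) for p in posts],
                    "group": [tertiles.assignment[p.post_id] for p in posts],
                }
            ),
        )

        stage = "tfidf"
        corpora = _tertile_corpora(posts, tertiles.assignment, token_config)
        table = text_prep.tfidf_by_group(corpora)
        tfidf_rows = [
            {"group": g, "term": t, "weight": w}
            for g in text_prep.GROUPS
            for t, w in text_prep.top_terms(table.group(g), config.top_k_terms)
        ]
        write_csv("tfidf_terms", pd.DataFrame(tfidf_rows))

        stage = "keyness"
        corpus_a = text_prep.build_corpus([p.message for p in posts], token_config)
        corpus_b = text_prep.build_corpus([reference_text], token_config)
        ranked = corpus_compare.rank_keywords(corpus_a, corpus_b, config.min_count)
        write_csv(
            "keyness",
            pd.DataFrame(
                [
                    {
                        "term": r.term,
                        "ll": round(r.ll, 1),
                        "count_posts": r.a,
                        "count_reference": r.b,
                        "direction": r.direction.value,
                    }
                    for r in ranked
                ]
            ),
        )

        stage = "sentiment"
        scores = sentiment.score_posts(posts, lexicon)
        write_csv(
            "sentiment",
            pd.DataFrame(
                [
                    {
                        "post_id": pid,
                        "polarity": s.polarity,
                        "subjectivity": s.subjectivity,
                        "matched_terms": s.matched_terms,
                    }
                    for pid, s in scores.items()
                ]
            ),
        )

        stage = "temporal"
        polarity = {pid: s.polarity for pid, s in scores.items()}
        eng = {p.post_id: float(engagement(p)) for p in posts}
        write_csv(
            "temporal_hour_polarity",
            temporal.aggregate(posts, polarity, "hour", "polarity"),
        )
        write_csv(
            "temporal_daypart_polarity",
            temporal.aggregate(posts, polarity, "daypart", "polarity"),
        )
        write_csv(
            "temporal_hour_engagement",
            temporal.aggregate(posts, eng, "hour", "engagement"),
        )

        stage = "correlations"
        cells = association.correlation_matrix(scores, posts)
        write_csv("correlations", association.matrix_frame(cells))

        stage = "summary"
        anova_pol_hour = temporal.one_way_anova(
            [polarity[p.post_id] for p in posts],
            [p.created.hour for p in posts],
        )
        summary = {
            "n_posts": len(posts),
            "tertile_thresholds": {
                "q_low": tertiles.q_low,
                "q_high": tertiles.q_high,
            },
            "corpus_tokens": {
                "posts": corpus_a.total_tokens,
                "reference": corpus_b.total_tokens,
            },
            "top_keyness": [
                {"term": r.term, "ll": r.ll, "direction": r.direction.value}
                for r in ranked[:12]
            ],
            "anova_polarity_hour": {
                "F": anova_pol_hour[0],
                "p": anova_pol_hour[1],
            },
        }
        path = out / "summary.json"
        path.write_text(json.dumps(summary, indent=2, ensure_ascii=False))
        outputs["summary"] = path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return outputs
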