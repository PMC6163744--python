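"""Reading, writing and anonymizing post tables and reference documents.

The on-disk post table is the tab-separated export dialect produced by
Facebook group-export tools: one header row, one data row per post, with a
post identifier, a post type, the message text, a creation timestamp and
the interaction counts (likes, comments, shares, reactions).  Column names
are remappable through :class:`TableDialect` because exports from different
tool versions used different headers.

Anonymization happens here, before any downstream text processing: e-mail
addresses are masked by pattern, personal names only from an explicit
user-supplied list (no NER — deterministic and testable).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

logger = logging.getLogger(__name__)

#: The six post types a Facebook group export can contain.
POST_TYPES = ("event", "link", "note", "photo", "status", "video")

#: Default timezone for naive timestamps: the study population's zone.
DEFAULT_TIMEZONE = "Europe/Madrid"

_COUNT_FIELDS = ("likes", "comments", "shares", "reactions")


class ConfigurationError(ValueError):
    """A required column or option is missing or malformed."""


class RowError(ValueError):
    """A data row violates the post invariants (carries the row number)."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


class InputError(ValueError):
    """An input file is unreadable, empty or otherwise unusable."""


@dataclass(frozen=True)
class Post:
    """One social-media post.

    ``reactions`` counts all six reaction types (love, haha, wow, sad,
    angry and the classic like), so ``reactions >= likes`` always holds.
    """

    post_id: str
    post_type: str
    message: str
    created: datetime
    likes: int
    comments: int
    shares: int
    reactions: int

    def __post_init__(self) -> None:
        if self.post_type not in POST_TYPES:
            raise ValueError(f"unknown post type {self.post_type!r}")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.reactions < self.likes:
            raise ValueError(
                f"reactions ({self.reactions}) < likes ({self.likes}): "
                "likes are one of the reaction types"
            )
        if self.created.tzinfo is None:
            raise ValueError("created must be timezone-aware")


@dataclass(frozen=True)
class TableDialect:
    """Shape of the post-table file.

    ``columns`` maps canonical field names (``post_id``, ``post_type``,
    ``message``, ``created``, ``likes``, ``comments``, ``shares``,
    ``reactions``) to the header names used in the file.  ``type_map``
    optionally maps non-standard type strings onto the six canonical ones.
    Naive timestamps are localized to ``timezone``.
    """

    delimiter: str = "\t"
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "post_id": "post_id",
            "post_type": "type",
            "message": "message",
            "created": "created_time",
            "likes": "likes_count",
            "comments": "comments_count",
            "shares": "shares_count",
            "reactions": "reactions_count",
        }
    )
    timezone: str = DEFAULT_TIMEZONE
    type_map: dict[str, str] = field(default_factory=dict)


DEFAULT_DIALECT = TableDialect()


def _parse_timestamp(raw: str, tz: ZoneInfo) -> datetime:
    ts = datetime.fromisoformat(raw)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=tz)
    return ts


def read_posts(
    path,
    dialect: TableDialect = DEFAULT_DIALECT,
    *,
    lenient: bool = False,
) -> list[Post]:
    """Read a post table into a list of :class:`Post`, in file order.

    Strict mode (default) raises :class:`RowError` on the first bad row;
    with ``lenient=True`` bad rows are logged and skipped instead.
    Missing required columns always raise :class:`ConfigurationError`.
    """
    df = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    for canonical, header in dialect.columns.items():
        if header not in df.columns:
            raise ConfigurationError(
                f"required column {header!r} (for field {canonical!r}) not in header"
            )
    tz = ZoneInfo(dialect.timezone)
    posts: list[Post] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        record = dict(zip(df.columns, row))
        try:
            raw_type = record[dialect.columns["post_type"]]
            post_type = dialect.type_map.get(raw_type, raw_type)
            counts = {}
            for name in _COUNT_FIELDS:
                raw = record[dialect.columns[name]]
                counts[name] = int(raw)
            posts.append(
                Post(
                    post_id=record[dialect.columns["post_id"]],
                    post_type=post_type,
                    message=record[dialect.columns["message"]],
                    created=_parse_timestamp(record[dialect.columns["created"]], tz),
                    **counts,
                )
            )
        except (ValueError, KeyError) as exc:
            if lenient:
                logger.warning("skipping row %d: %s", i, exc)
                continue
            raise RowError(i, str(exc)) from exc
    return posts


def write_posts(posts: Iterable[Post], path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
    """Write posts in the same table dialect :func:`read_posts` reads."""
    cols = dialect.columns
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        order = ("post_id", "post_type", "message", "created", *_COUNT_FIELDS)
        writer.writerow([cols[c] for c in order])
        for p in posts:
            writer.writerow(
                [
                    p.post_id,
                    p.post_type,
                    p.message,
                    p.created.isoformat(),
                    p.likes,
                    p.comments,
                    p.shares,
                    p.reactions,
                ]
            )


def read_reference_document(path) -> str:
    """Read a plain-text reference document (e.g. a priority decalogue).

    Returns the full text unchanged; normalization is the tokenizer's job.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read reference document {path}: {exc}") from exc
    if not text.strip():
        raise InputError(f"reference document {path} is empty")
    return text


# RFC-ish e-mail shape; intentionally simple and deterministic.
EMAIL_PATTERN = re.compile(r"[\w.+-]+@[\w-]+(?:\.[\w-]+)+", re.UNICODE)

EMAIL_PLACEHOLDER = "<EMAIL>"
NAME_PLACEHOLDER = "<NAME>"


@dataclass(frozen=True)
class MaskingRules:
    """What to mask in message text.

    ``names`` is an explicit list of personal names to replace (matched
    case-insensitively on word boundaries).  E-mail masking is always on
    unless ``mask_emails=False``.
    """

    names: Sequence[str] = ()
    mask_emails: bool = True
    email_placeholder: str = EMAIL_PLACEHOLDER
    name_placeholder: str = NAME_PLACEHOLDER


def _mask_text(text: str, rules: MaskingRules) -> str:
    if rules.mask_emails:
        text = EMAIL_PATTERN.sub(rules.email_placeholder, text)
    for name in rules.names:
        if not name:
            continue
        # lookarounds keep already-inserted <...> placeholders intact,
        # which makes repeated application a no-op
        pattern = re.compile(
            rf"(?<!<)\b{re.escape(name)}\b(?!>)", re.IGNORECASE | re.UNICODE
        )
        text = pattern.sub(rules.name_placeholder, text)
    return text


def anonymize(posts: Iterable[Post], rules: MaskingRules = MaskingRules()) -> list[Post]:
    """Mask e-mail addresses and listed personal names in message text.

    Pure and idempotent; counts, timestamps and post types are untouched.
    """
    return [replace(p, message=_mask_text(p.message, rules)) for p in posts]
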