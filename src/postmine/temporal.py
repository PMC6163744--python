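"""Temporal aggregation: hour/weekday extraction, dayparts, one-way ANOVA.

All clock arithmetic happens in the timestamps' own timezone (posts read
through :mod:`postmine.corpus_io` carry one).  Dayparts are the four
six-hour bands morning [6, 12), afternoon [12, 18), evening [18, 24) and
night [0, 6); bins are half-open, so a post at exactly 12:00 is
afternoon.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Post

DAYPARTS = ("morning", "afternoon", "evening", "night")
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def daypart(hour: int) -> str:
    """Map an hour of day onto its six-hour band."""
    if not 0 <= hour <= 23:
        raise ValueError(f"hour {hour} outside 0-23")
    if 6 <= hour < 12:
        return "morning"
    if 12 <= hour < 18:
        return "afternoon"
    if 18 <= hour < 24:
        return "evening"
    return "night"


_KEY_DOMAIN: dict[str, Sequence] = {
    "hour": tuple(range(24)),
    "weekday": WEEKDAYS,
    "daypart": DAYPARTS,
}


def _key_of(post: Post, by: str):
    if by == "hour":
        return post.created.hour
    if by == "weekday":
        return WEEKDAYS[post.created.weekday()]
    if by == "daypart":
        return daypart(post.created.hour)
    if by == "post_type":
        return post.post_type
    raise ValueError(f"unknown aggregation key {by!r}")


def aggregate(
    posts: Sequence[Post],
    metric: Mapping[str, float] | Sequence[float],
    by: str,
    metric_name: str = "metric",
) -> pd.DataFrame:
    """Per-key post counts and metric means.

    ``metric`` is either a post_id-keyed mapping or a sequence aligned
    with ``posts``.  Keys with no posts are reported with n = 0 and a NaN
    mean (hour, weekday and daypart keys are exhaustive; post_type keys
    cover the observed types).  Returns a DataFrame with columns
    ``key``, ``n``, ``mean_<metric_name>``.
    """
    if isinstance(metric, Mapping):
        values = [float(metric[p.post_id]) for p in posts]
    else:
        if len(metric) != len(posts):
            raise ValueError("metric sequence not aligned with posts")
        values = [float(v) for v in metric]
    buckets: dict[object, list[float]] = {}
    for p, v in zip(posts, values):
        buckets.setdefault(_key_of(p, by), []).append(v)
    domain = _KEY_DOMAIN.get(by, sorted(buckets))
    rows = []
    for key in domain:
        vals = buckets.get(key, [])
        rows.append(
            {
                "key": key,
                "n": len(vals),
                f"mean_{metric_name}": float(np.mean(vals)) if vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def hourly_frequency(posts: Sequence[Post]) -> pd.DataFrame:
    """Post counts per hour of day (0-23), zeros included."""
    out = aggregate(posts, [0.0] * len(posts), by="hour", metric_name="unused")
    return out[["key", "n"]].rename(columns={"key": "hour"})


def one_way_anova(
    values: Sequence[float], labels: Sequence
) -> tuple[float, float]:
    """Classical one-way ANOVA of ``values`` grouped by ``labels``.

    Returns (F, upper-tail p).  All-identical observations give
    (0.0, 1.0) — no variance to apportion; fewer than 2 groups or no
    residual degrees of freedom raise.
    """
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    groups: dict[object, list[float]] = {}
    for v, lab in zip(values, labels):
        groups.setdefault(lab, []).append(float(v))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = list(groups.values())
    n = len(values)
    if n - len(groups) < 1:
        raise ValueError("no residual degrees of freedom")
    arr = np.asarray(values, dtype=float)
    if np.ptp(arr) == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    if np.isnan(f):  # zero within-group variance with distinct means
        return float("inf"), 0.0
    return float(f), float(p)
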