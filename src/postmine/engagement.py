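"""Engagement metric and tertile stratification.

Engagement of a post is the sum of its comments, shares and reactions.
Likes are NOT added separately: the reactions count already contains the
classic like alongside love/haha/wow/sad/angry, so adding likes would
double-count them.

Posts are split at the 33rd and 67th percentiles of engagement into
low / medium / high groups, the unit the tf-idf vocabulary selection
operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus_io import Post

TERTILE_LABELS = ("low", "medium", "high")


def engagement(post: Post) -> int:
    """comments + shares + reactions (likes live inside reactions)."""
    return post.comments + post.shares + post.reactions


@dataclass(frozen=True)
class EngagementTertiles:
    """Tertile thresholds plus the per-post group assignment."""

    q_low: float
    q_high: float
    assignment: Mapping[str, str]  # post_id -> low | medium | high

    def group_ids(self, label: str) -> list[str]:
        return [pid for pid, g in self.assignment.items() if g == label]


def _nearest_rank(sorted_values: Sequence[int], fraction: float) -> float:
    """Nearest-rank percentile: value at rank ceil(fraction * n), 1-indexed."""
    n = len(sorted_values)
    rank = max(1, math.ceil(fraction * n))
    return float(sorted_values[rank - 1])


def tertile_split(posts: Sequence[Post]) -> EngagementTertiles:
    """Assign each post to a low / medium / high engagement tertile.

    Thresholds are nearest-rank percentiles of the engagement values:
    q_low at the 33rd and q_high at the 67th.  A post is low when its
    engagement is <= q_low, high when > q_high, medium otherwise — so
    boundary ties all fall to the lower group, deterministically.  In the
    degenerate case q_low == q_high (heavily tied or constant data) posts
    at the shared threshold are medium, below it low, above it high.
    """
    if len(posts) < 3:
        raise ValueError("tertile split needs at least 3 posts")
    values = sorted(engagement(p) for p in posts)
    q_low = _nearest_rank(values, 1 / 3)
    q_high = _nearest_rank(values, 2 / 3)
    assignment: dict[str, str] = {}
    for p in posts:
        e = engagement(p)
        if q_low == q_high:
            label = "low" if e < q_low else ("high" if e > q_high else "medium")
        elif e <= q_low:
            label = "low"
        elif e > q_high:
            label = "high"
        else:
            label = "medium"
        assignment[p.post_id] = label
    return EngagementTertiles(q_low=q_low, q_high=q_high, assignment=assignment)
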