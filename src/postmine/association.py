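"""Spearman correlation screen between sentiment and interaction counts.

Interaction counts are heavily tied, so rank correlation with average
ranks is the appropriate measure; p-values use the t-approximation on
n - 2 degrees of freedom.  Cells with |rho| >= 0.10 are flagged as
noteworthy — a pragmatic effect-size floor for screening, not a
significance test (no multiple-testing correction is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Post
from .engagement import engagement
from .sentiment import SentimentScore

HIGHLIGHT_THRESHOLD = 0.10

ROW_VARS = ("polarity", "subjectivity")
COL_VARS = ("likes", "comments", "reactions", "shares", "engagement")


@dataclass(frozen=True)
class CorrelationCell:
    row_var: str
    col_var: str
    rho: float
    p_value: float

    @property
    def highlighted(self) -> bool:
        return abs(self.rho) >= HIGHLIGHT_THRESHOLD


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlation_matrix(
    scores: Mapping[str, SentimentScore], posts: Sequence[Post]
) -> list[CorrelationCell]:
    """The 2x5 grid: polarity & subjectivity vs the interaction counts."""
    rows = {
        "polarity": [scores[p.post_id].polarity for p in posts],
        "subjectivity": [scores[p.post_id].subjectivity for p in posts],
    }
    cols = {
        "likes": [p.likes for p in posts],
        "comments": [p.comments for p in posts],
        "reactions": [p.reactions for p in posts],
        "shares": [p.shares for p in posts],
        "engagement": [engagement(p) for p in posts],
    }
    cells = []
    for rv in ROW_VARS:
        for cv in COL_VARS:
            rho, p = spearman(rows[rv], cols[cv])
            cells.append(CorrelationCell(rv, cv, rho, p))
    return cells


def matrix_frame(cells: Sequence[CorrelationCell]) -> pd.DataFrame:
    """Long-format DataFrame of the correlation grid."""
    return pd.DataFrame(
        [
            {
                "row_var": c.row_var,
                "col_var": c.col_var,
                "rho": c.rho,
                "p_value": c.p_value,
                "highlighted": c.highlighted,
            }
            for c in cells
        ]
    )
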