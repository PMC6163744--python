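"""Corpus keyness: contingency tables and the two-term log-likelihood score.

Two corpora A and B are compared term by term through the contingency
row (a, b, c, d): a and b are the term's counts in A and B, c and d the
corpora's total token counts.  Expected counts under the null of equal
relative frequency are

    E1 = c (a + b) / (c + d),      E2 = d (a + b) / (c + d)

and the keyness score is the two-term log-likelihood

    LL = 2 (a ln(a / E1) + b ln(b / E2)),

with the convention 0 * ln(0 / E) := 0 so single-corpus terms score
finitely.  LL is 0 exactly when a/c = b/d and grows as the term's
relative frequencies diverge; the enrichment direction records which
corpus over-uses the term.  (This is the two-term form as used in the
word-keyness literature, not the four-term G² statistic; the four-term
variant is available behind a flag.)

``calibrate_ratio`` inverts the statistic: because LL depends on (c, d)
only through p = c/(c+d), the unpublished corpus-size ratio behind a
printed keyness table can be recovered from its (a, b, LL) rows by 1-D
least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from scipy.optimize import minimize_scalar

from .text_prep import Corpus


class Direction(Enum):
    """Which corpus over-uses the term, by relative frequency."""

    A_ENRICHED = "A-enriched"
    B_ENRICHED = "B-enriched"
    BALANCED = "balanced"


@dataclass(frozen=True)
class ContingencyRow:
    """One term's 2x2 table margins: counts a, b and corpus totals c, d."""

    term: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.c and 0 <= self.b <= self.d):
            raise ValueError(
                f"{self.term!r}: need 0 <= a <= c and 0 <= b <= d, "
                f"got a={self.a}, b={self.b}, c={self.c}, d={self.d}"
            )
        if self.c + self.d <= 0:
            raise ValueError("both corpora are empty (c + d = 0)")
        if self.a + self.b < 1:
            raise ValueError(f"{self.term!r}: term absent from both corpora")


@dataclass(frozen=True)
class LLResult:
    """Keyness score and enrichment direction for one term."""

    term: str
    a: int
    b: int
    e1: float
    e2: float
    ll: float
    direction: Direction


def expected_counts(row: ContingencyRow) -> tuple[float, float]:
    """Expected term counts (E1, E2) under equal relative frequency.

    E1 + E2 = a + b by construction.
    """
    n = row.a + row.b
    total = row.c + row.d
    return row.c * n / total, row.d * n / total


def _xlogx_ratio(count: int, expected: float) -> float:
    # the 0 * ln(0/E) := 0 convention
    if count == 0:
        return 0.0
    return count * math.log(count / expected)


def log_likelihood(row: ContingencyRow, *, four_term: bool = False) -> LLResult:
    """Score one contingency row.

    The default is the two-term form; ``four_term=True`` adds the
    "other words" cells (the textbook G² statistic) for comparison.
    """
    e1, e2 = expected_counts(row)
    ll = 2.0 * (_xlogx_ratio(row.a, e1) + _xlogx_ratio(row.b, e2))
    if four_term:
        rest_a, rest_b = row.c - row.a, row.d - row.b
        ll += 2.0 * (
            _xlogx_ratio(rest_a, row.c - e1) + _xlogx_ratio(rest_b, row.d - e2)
        )
    freq_a = row.a / row.c if row.c else 0.0
    freq_b = row.b / row.d if row.d else 0.0
    if freq_a > freq_b:
        direction = Direction.A_ENRICHED
    elif freq_a < freq_b:
        direction = Direction.B_ENRICHED
    else:
        direction = Direction.BALANCED
    # two-term LL is analytically >= 0; clip the float noise at the minimum
    return LLResult(row.term, row.a, row.b, e1, e2, max(ll, 0.0), direction)


def rank_keywords(
    corpus_a: Corpus,
    corpus_b: Corpus,
    min_count: int = 1,
    *,
    four_term: bool = False,
) -> list[LLResult]:
    """Score every union-vocabulary term with a+b >= min_count.

    Sorted by descending LL, ties broken lexicographically by term.
    """
    c, d = corpus_a.total_tokens, corpus_b.total_tokens
    if c == 0 or d == 0:
        raise ValueError("both corpora must be non-empty")
    vocabulary = set(corpus_a.term_counts) | set(corpus_b.term_counts)
    results = []
    for term in vocabulary:
        a, b = corpus_a.count(term), corpus_b.count(term)
        if a + b < min_count:
            continue
        results.append(
            log_likelihood(ContingencyRow(term, a, b, c, d), four_term=four_term)
        )
    results.sort(key=lambda r: (-r.ll, r.term))
    return results


def ll_at_ratio(a: int, b: int, p: float) -> float:
    """Two-term LL as a function of the corpus-size ratio p = c/(c+d).

    With n = a + b the expected counts are E1 = n p and E2 = n (1 - p);
    the totals c, d enter the score only through p.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    n = a + b
    ll = 2.0 * (_xlogx_ratio(a, n * p) + _xlogx_ratio(b, n * (1.0 - p)))
    return max(ll, 0.0)


@dataclass(frozen=True)
class CalibrationResult:
    """Recovered corpus-size ratio and per-row LL discrepancies."""

    p_hat: float
    residuals: tuple[float, ...]  # model LL minus printed LL, row order

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals)


def calibrate_ratio(
    rows: Sequence[tuple[int, int, float]],
    *,
    bounds: tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> CalibrationResult:
    """Recover p = c/(c+d) from printed (a, b, LL) keyness rows.

    Minimizes the summed squared difference between the two-term LL
    evaluated at p and the printed scores, by bounded scalar minimization.
    """
    if not any(ll > 0 for _, _, ll in rows):
        raise ValueError("calibration needs at least one row with LL > 0")

    def sse(p: float) -> float:
        return sum((ll_at_ratio(a, b, p) - ll) ** 2 for a, b, ll in rows)

    opt = minimize_scalar(
        sse, bounds=bounds, method="bounded", options={"xatol": 1e-12}
    )
    p_hat = float(opt.x)
    if not bounds[0] < p_hat < bounds[1] or not opt.success:
        raise ValueError("no interior ratio fits the printed rows")
    residuals = tuple(ll_at_ratio(a, b, p_hat) - ll for a, b, ll in rows)
    return CalibrationResult(p_hat=p_hat, residuals=residuals)
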