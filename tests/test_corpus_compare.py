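import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postmine import (
    ContingencyRow,
    Corpus,
    Direction,
    calibrate_ratio,
    expected_counts,
    ll_at_ratio,
    log_likelihood,
    rank_keywords,
)


class TestExpectedCounts:
    def test_hand_evaluation(self):
        e1, e2 = expected_counts(ContingencyRow("nacional", 32, 9, 9665, 335))
        assert e1 == pytest.approx(39.63, abs=0.01)
        assert e2 == pytest.approx(1.37, abs=0.01)

    def test_symmetry_when_totals_equal(self):
        e1, e2 = expected_counts(ContingencyRow("t", 7, 3, 100, 100))
        assert e1 == e2 == 5.0

    def test_depends_only_on_marginals(self):
        e1, e2 = expected_counts(ContingencyRow("t", 0, 5, 100, 100))
        assert (e1, e2) == (2.5, 2.5)

    def test_e1_plus_e2_equals_a_plus_b(self):
        row = ContingencyRow("t", 13, 4, 977, 311)
        e1, e2 = expected_counts(row)
        assert e1 + e2 == pytest.approx(row.a + row.b, rel=1e-12)

    @pytest.mark.parametrize(
        "a,b,c,d", [(5, 0, 3, 10), (0, 5, 10, 3), (-1, 2, 10, 10), (0, 0, 5, 5)]
    )
    def test_invalid_rows_rejected(self, a, b, c, d):
        with pytest.raises(ValueError):
            ContingencyRow("t", a, b, c, d)


class TestLogLikelihood:
    def test_balanced_frequencies_score_zero(self):
        res = log_likelihood(ContingencyRow("t", 97, 3, 9700, 300))
        assert res.ll == 0.0
        assert res.direction is Direction.BALANCED

    def test_zero_count_convention_closed_form(self):
        # a=10, b=0, equal totals: LL = 2 * 10 * ln 2
        res = log_likelihood(ContingencyRow("t", 10, 0, 100, 100))
        assert res.ll == pytest.approx(20 * math.log(2), rel=1e-12)
        assert res.direction is Direction.A_ENRICHED

    def test_direction_tracks_relative_frequency(self):
        res = log_likelihood(ContingencyRow("t", 1, 9, 1000, 100))
        assert res.direction is Direction.B_ENRICHED

    def test_scaling_preserves_balance_only(self):
        balanced = ContingencyRow("t", 10, 5, 200, 100)
        assert log_likelihood(balanced).ll == 0.0
        scaled = ContingencyRow("t", 30, 15, 600, 300)
        assert log_likelihood(scaled).ll == 0.0
        unbalanced = log_likelihood(ContingencyRow("t", 30, 5, 600, 300)).ll
        assert unbalanced > 0

    def test_grows_away_from_expected(self):
        # fixed margins, sweep a: minimum at the balanced split
        lls = [
            log_likelihood(ContingencyRow("t", a, 20 - a, 300, 300)).ll
            for a in range(21)
        ]
        assert min(lls) == lls[10]
        assert all(lls[i] >= lls[i + 1] for i in range(10))  # decreasing to center
        assert all(lls[i] <= lls[i + 1] for i in range(10, 20))

    def test_four_term_variant_scores_higher(self):
        row = ContingencyRow("t", 32, 9, 9665, 335)
        assert (
            log_likelihood(row, four_term=True).ll > log_likelihood(row).ll
        )

    @settings(deadline=None, max_examples=100)
    @given(
        st.integers(0, 50),
        st.integers(0, 50),
        st.integers(51, 5000),
        st.integers(51, 5000),
    )
    def test_always_non_negative(self, a, b, c, d):
        if a + b == 0:
            return
        assert log_likelihood(ContingencyRow("t", a, b, c, d)).ll >= 0.0


def brute_force_rank(corpus_a, corpus_b, min_count=1):
    """Independent re-evaluation of the score over the union vocabulary."""
    c = sum(corpus_a.term_counts.values())
    d = sum(corpus_b.term_counts.values())
    out = []
    for term in set(corpus_a.term_counts) | set(corpus_b.term_counts):
        a = corpus_a.term_counts.get(term, 0)
        b = corpus_b.term_counts.get(term, 0)
        if a + b < min_count:
            continue
        e1 = c * (a + b) / (c + d)
        e2 = d * (a + b) / (c + d)
        ll = 0.0
        if a:
            ll += a * math.log(a / e1)
        if b:
            ll += b * math.log(b / e2)
        out.append((term, 2 * ll))
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out


class TestRankKeywords:
    def test_single_unbalanced_term_ranks_first(self):
        corpus_a = Corpus({"igual": 50, "raro": 20})
        corpus_b = Corpus({"igual": 50, "raro": 2})
        ranked = rank_keywords(corpus_a, corpus_b)
        assert ranked[0].term == "raro"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        vocab = [f"w{i}" for i in range(100)]
        counts_a = {w: int(rng.integers(0, 30)) for w in vocab}
        counts_b = {w: int(rng.integers(0, 10)) for w in vocab}
        corpus_a = Corpus({w: c for w, c in counts_a.items() if c})
        corpus_b = Corpus({w: c for w, c in counts_b.items() if c})
        ranked = rank_keywords(corpus_a, corpus_b, min_count=2)
        oracle = brute_force_rank(corpus_a, corpus_b, min_count=2)
        assert [(r.term, r.ll) for r in ranked] == [
            (t, pytest.approx(ll, rel=1e-12, abs=1e-12)) for t, ll in oracle
        ]

    def test_min_count_filters_union_counts(self):
        corpus_a = Corpus({"uno": 1, "dos": 2})
        corpus_b = Corpus({"dos": 1, "tres": 3})
        terms = {r.term for r in rank_keywords(corpus_a, corpus_b, min_count=3)}
        assert terms == {"dos", "tres"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            rank_keywords(Corpus({}), Corpus({"a": 1}))


class TestCalibrateRatio:
    def test_single_row_inversion(self):
        cal = calibrate_ratio([(53, 9, 13.4)])
        assert ll_at_ratio(53, 9, cal.p_hat) == pytest.approx(13.4, abs=0.05)

    def test_parameter_recovery_at_known_ratio(self):
        p_true = 0.9
        rows = [
            (a, b, ll_at_ratio(a, b, p_true))
            for a, b in [(32, 9), (53, 9), (195, 1), (28, 5), (190, 2)]
        ]
        cal = calibrate_ratio(rows)
        assert cal.p_hat == pytest.approx(p_true, abs=0.005)
        assert cal.max_abs_residual < 1e-4

    def test_all_zero_ll_rows_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ratio([(10, 10, 0.0)])

    def test_ll_at_ratio_matches_contingency_form(self):
        # p = c/(c+d) carries all the information the totals contribute
        row = ContingencyRow("t", 21, 4, 8000, 250)
        p = row.c / (row.c + row.d)
        assert ll_at_ratio(row.a, row.b, p) == pytest.approx(
            log_likelihood(row).ll, rel=1e-12
        )
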