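"""Published benchmark rows for validating the keyness implementation.

A study of Spanish rare-disease Facebook groups published the twelve
highest-scoring keyness rows (term, two-term log-likelihood, term count
in the post corpus, term count in the reference priority document) from
a comparison of roughly 3900 group posts against the national
federation's priority decalogue.  The corpus token totals were not
published — but the two-term LL depends on them only through the ratio
p = c/(c+d), which :func:`postmine.calibrate_ratio` recovers from the
rows themselves.  These rows therefore double as a strong structural
check: a single ratio must reproduce every printed score at once.

Each row is (term, printed_ll, count_posts, count_reference).
"""

from __future__ import annotations

KEYNESS_TOP12: tuple[tuple[str, float, int, int], ...] = (
    ("nacional", 20.2, 32, 9),
    ("discapacidad", 13.4, 53, 9),
    ("nivel", 7.8, 28, 5),
    ("ayuda", 7.5, 195, 1),
    ("profesionales", 6.1, 23, 4),
    ("referencia", 5.0, 28, 4),
    ("vida", 4.3, 190, 2),
    ("frecuentes", 3.8, 35, 4),
    ("enfermedades", 3.3, 192, 12),
    ("ser", 3.2, 167, 2),
    ("personas", 3.0, 206, 3),
    ("hijo", 3.0, 112, 1),
)

#: Same study, lowest-scoring rows (near-balanced relative frequencies).
KEYNESS_BOTTOM10: tuple[tuple[str, float, int, int], ...] = (
    ("causa", 0.063, 48, 2),
    ("social", 0.051, 36, 1),
    ("difundir", 0.047, 23, 1),
    ("medio", 0.031, 24, 1),
    ("experiencias", 0.027, 34, 1),
    ("forma", 0.021, 52, 2),
    ("general", 0.01, 32, 1),
    ("cuanto", 0.01, 26, 1),
    ("todas", 0.007, 91, 3),
    ("dice", 0.000014, 29, 1),
)

#: Status-post component means from the same study's characterization
#: table: (comments, shares, reactions) and the engagement they sum to.
STATUS_COMPONENT_MEANS = {"comments": 2.9, "shares": 0.1, "reactions": 4.7}
STATUS_ENGAGEMENT_MEAN = 7.7
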