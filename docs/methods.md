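# Methods

## Scope and data model

The unit of analysis is a **post**: an opaque id, one of six types
(event, link, note, photo, status, video), a unicode message, a
timezone-aware creation timestamp, and four non-negative interaction
counts. The invariant `reactions >= likes` is enforced at construction:
the platform's reactions count aggregates love/haha/wow/sad/angry *and*
the classic like, so likes are a subset of reactions. Naive timestamps
in input files are localized to a configurable zone (default
Europe/Madrid, the population the pipeline was built for); every
hour-of-day result depends on this choice, which is why it is a single
explicit knob rather than an implicit assumption.

Anonymization is deliberately mechanical: e-mail addresses by regular
expression, personal names only from a caller-supplied list. A named-entity
recognizer would catch more but would make the transformation
non-deterministic across model versions; a masking step that feeds a
published analysis must be reproducible. The operation is idempotent
(placeholders are protected from re-matching), so re-running a pipeline
over already-masked data is safe.

## Engagement and stratification

Engagement is `comments + shares + reactions`. Adding likes separately
would double-count them (see above); the characterization table's
engagement means must equal the sum of the three component means, and the
test suite checks this linearity exactly.

The tertile split uses nearest-rank percentiles (the value at rank
`ceil(f·n)`, 1-indexed) at f = 1/3 and 2/3. Count data are heavily tied,
so the rule must say where boundary ties go: a post is *low* when
engagement ≤ q_low, *high* when > q_high, otherwise *medium* — ties at a
threshold fall toward the lower group. When the two thresholds coincide
(degenerate, heavily tied or constant data) posts at the shared value are
*medium*, so a constant-engagement corpus is all-medium rather than
all-low. With continuous-like engagement values the groups come out
within a percent of a third each; with realistic tied counts the low
group absorbs the boundary ties, which is documented behavior, not error.

## tf-idf over engagement groups

The document set for idf is exactly the three concatenated tertile
corpora (N = 3), natural logarithm. The point of this unusual choice is
the filter it implies: a term occurring at all three engagement levels
has idf ln(3/3) = 0 and vanishes from every group's vocabulary, leaving
only level-distinctive terms. For a single document (e.g. the reference
decalogue) raw frequency is used instead — idf over one document is
vacuous. Tokens are Unicode word sequences of length ≥ 2, lowercased,
accents preserved (Spanish vocabulary is accent-bearing); URLs and
@handles are stripped first because spam posts otherwise dominate the
low-engagement vocabulary. A default Spanish stopword list ships with the
package; common verb infinitives (ser, estar, tener…) are deliberately
*not* stopworded because they carry content in this domain.

## Keyness

For term counts a, b in corpora of c, d total tokens, expected counts
are E1 = c(a+b)/(c+d) and E2 = d(a+b)/(c+d), and the score is the
**two-term** log-likelihood LL = 2(a·ln(a/E1) + b·ln(b/E2)) with the
convention 0·ln(0/E) := 0 so single-corpus terms score finitely. The
textbook four-term G² (which adds the "other words" cells) is available
behind a flag but is not the default: the published benchmark rows this
package validates against are numerically consistent with the two-term
form as printed (a single corpus ratio reproduces all twelve printed
scores to within 0.04 LL units). LL is reported
as a ranking score, not a p-value, and no multiple-testing correction is
applied. Ranking covers the union vocabulary with a configurable minimum
pooled count (default 1) and lexicographic tie-break.

**Ratio calibration.** Writing p = c/(c+d), the score becomes
LL(a, b; p) = 2(a·ln(a/((a+b)p)) + b·ln(b/((a+b)(1−p)))) — the totals
enter only through p. Given published (a, b, LL) rows whose totals were
not published, bounded scalar least squares over p ∈ (0, 1) recovers the
ratio; per-row residuals diagnose whether one consistent ratio exists at
all. The recovered p̂ is an estimate, not a published quantity.

## Sentiment

A transparent lexicon scorer with the range semantics polarity ∈ [−1, 1],
subjectivity ∈ [0, 1]: per-text scores are means over matched lexicon
terms, clamped to the declared ranges, (0, 0) when nothing matches. A
negator within the 3 tokens preceding a match multiplies its polarity by
−0.5 ("not good" is mildly negative, not the mirror of "good");
intensifiers multiply by their configured factor before clamping. These
constants are conventional and fixed so that every score is exactly
reproducible — the goal is a documented, testable scorer, not a
re-implementation of any trained toolkit lexicon, whose magnitudes are
toolkit-specific. Accordingly only score *signs*, never magnitudes, are
treated as comparable across scorers. Scoring tokenizes without stopword
removal (negators are function words) and works in the text's own
language against a matching lexicon; no machine-translation step is
involved. The bundled lexicon is a small bilingual (Spanish/English)
starter set.

## Temporal analysis

Dayparts are half-open six-hour bands: morning [6, 12), afternoon
[12, 18), evening [18, 24), night [0, 6); exactly 12:00 is afternoon (the
interval notation in prose is ambiguous at endpoints, so one convention
is fixed and tested). Aggregation reports per-key counts and arithmetic
means with empty keys kept (n = 0, NaN mean) so 24-hour profiles are
always complete; counts are conserved by construction. One-way ANOVA is
the classical F test (scipy's implementation) with two documented edge
cases: all-identical observations return (F = 0, p = 1), and zero
within-group variance with distinct means returns (inf, 0). Hour can be
used as a 24-level factor or collapsed to dayparts; both are exposed.

## Association screen

Spearman rank correlation with average ranks (the count variables are
heavily tied) and the t-approximation on n − 2 degrees of freedom,
delegated to scipy. The 2×5 grid (polarity, subjectivity) × (likes,
comments, reactions, shares, engagement) flags cells with |ρ| ≥ 0.10 — an
effect-size screening floor, independent of the p-values, with no
multiple-testing correction.

## Synthetic data generator

The generator exists so that every stage has deterministic, license-free
inputs with the structure the analysis assumes. Defaults encode the
study conditions the package was built around:

- **Type mix**: multinomial with probabilities proportional to an
  observed corpus of 3917 posts (status 1787, link 1063, photo 792,
  video 232, event 34, note 9).
- **Counts**: per-type negative-binomial draws matched to observed
  (mean, std) pairs — observed std exceeds the mean everywhere, so a
  Poisson model would understate ties and tails; when std² ≤ mean the
  draw degrades to Poisson. Reactions are generated as
  `likes + extra_reactions`, making `reactions ≥ likes` true by
  construction rather than by rejection.
- **Diurnal rhythm**: 24 intensity weights with peaks at 13:00–15:00 and
  20:00–00:00 and the trough at 06:00.
- **Messages**: bags of words from a 32-term Spanish topic vocabulary.
  Six planted keywords get enrichment factors (reference-document weight
  = base weight × factor): three reference-enriched (factors 5–8), three
  post-enriched (factors ≈ 0.1), mirroring the qualitative finding the
  keyness stage is meant to surface.
- **Sentiment drift**: each post mixes in Poisson(2) sentiment words,
  positive with probability 0.5 + drift(hour), drift = +0.35 morning,
  +0.15 afternoon, −0.10 evening, −0.35 night — so mean polarity falls
  monotonically across the four dayparts.

A single integer seed drives one numpy `Generator` with a fixed per-post
draw order (type, timestamp, counts, message), so output is stable. The
reference document is drawn with seed + 1 from the enriched weights.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real message syntax (bags of words only), spam
bursts, correlation between message content and interaction counts
(except where a test plants one), weekday structure, follower-base
drift, or any coupling between post type and vocabulary. Recovery tests
demonstrate that the pipeline's estimators find planted structure at
realistic sizes, not that real corpora contain such structure.

## Numerical choices and problem sizes

Calibration uses bounded Brent minimization with xatol 1e-12; LL values
are clipped at 0 (the two-term form is analytically non-negative; floating
noise can dip below). Ranking and top-terms ties break lexicographically.
Report CSVs round LL and means to one decimal; the JSON summary keeps
full precision. Test simulations use 10,000–20,000 posts for sampling-
error bounds, 1000 replicates for the ANOVA type-I-error check, and the
full default corpus (3917 posts) for end-to-end recovery — sizes chosen
so every check is decisive at comfortable margins while the whole suite
runs in seconds.

## Known limitations

- The bundled lexicon is a toy; real analyses need a real lexicon file.
- No stemming/lemmatization: Spanish inflection spreads counts across
  forms, which deflates per-form keyness slightly.
- Nearest-rank tertiles with tie-to-lower assignment can produce markedly
  unequal groups on heavily tied engagement data (by design, documented).
- The p-value of the Spearman screen uses the t-approximation, adequate at
  the corpus sizes targeted (hundreds+) but rough below n ≈ 20; a
  permutation mode would be the fix if small-n use appears.
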