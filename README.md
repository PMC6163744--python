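# postmine

Content-based and temporal mining of social-media post exports, built for
studies of patient-community Facebook groups (e.g. Spanish rare-disease
associations) where the questions are: *which vocabulary distinguishes
high-engagement posts, how does the community's language compare with an
organization's official priority document, and when and with what sentiment
does the community post?*

The package takes a tab-separated post table (one row per post: type,
message, timestamp, like/comment/share/reaction counts — the export shape
of Netvizz-style tools) plus a plain-text reference document, and provides:

- **Engagement stratification.** Engagement of a post is
  `comments + shares + reactions` (likes are one of the six reaction types,
  so they are *not* added separately). Posts are split at the 33rd/67th
  nearest-rank percentiles into low/medium/high tertiles.
- **tf-idf vocabulary selection** with the three tertiles as the document
  set: `tfidf(t, g) = (count_t,g / tokens_g) · ln(3 / df_t)`, so a term
  used at every engagement level weighs exactly 0 and drops out.
- **Corpus keyness** between the post corpus A and the reference document B.
  For a term with counts *a*, *b* and corpus totals *c*, *d*:

  ```
  E1 = c(a+b)/(c+d)    E2 = d(a+b)/(c+d)
  LL = 2 ( a ln(a/E1) + b ln(b/E2) ),   with 0·ln(0/E) := 0
  ```

  the two-term log-likelihood keyness score, with the enrichment direction
  given by comparing relative frequencies a/c vs b/d. A calibration helper
  recovers the unpublished corpus-size ratio `p = c/(c+d)` from published
  (a, b, LL) rows by 1-D least squares — LL depends on the totals only
  through p.
- **Lexicon sentiment**: polarity in [−1, 1] and subjectivity in [0, 1] as
  clamped means over matched lexicon terms, with a 3-token negation window
  (factor −0.5) and multiplicative intensifiers. A small bilingual lexicon
  is bundled; supply a domain lexicon for real work.
- **Temporal analysis**: hour/weekday/daypart aggregation (morning [6,12),
  afternoon [12,18), evening [18,24), night [0,6)), post-frequency rhythms,
  one-way ANOVA.
- **Association screen**: Spearman correlations (average ranks, t-approximation
  p-values) between polarity/subjectivity and the interaction counts, with
  the |ρ| ≥ 0.10 highlighting rule.
- **Synthetic data generator** reproducing the statistical structure such a
  study assumes — six post types with overdispersed per-type count models,
  a bimodal diurnal rhythm (13:00–15:00 and 20:00–00:00 peaks), planted
  corpus-enriched keywords and an hour-dependent polarity drift — so the
  entire pipeline is testable without redistributable platform data.

## Worked example

```bash
postmine generate --n-posts 3917 --seed 42 --out demo
postmine keyness demo/posts.tsv demo/reference.txt --top 6
```

prints (term, LL, count in posts, count in reference, direction):

```
discapacidad    287.0   387     116     B-enriched
nacional        209.5   397     97      B-enriched
profesionales   137.5   415     78      B-enriched
ayuda           93.7    2051    5       A-enriched
vida            73.8    2083    10      A-enriched
hijo            69.2    1704    6       A-enriched
```

The generator plants exactly these six keywords: three over-represented in
the reference document ("B-enriched" — the community under-discusses them
relative to the official priorities) and three over-represented in the
posts ("A-enriched" — the community over-discusses them). All six are
recovered as the top six keyness terms. `postmine run-all` chains the full
pipeline (anonymize → characterize → tertiles → tf-idf → keyness →
sentiment → temporal → correlations) into a directory of CSV reports plus
a JSON summary; `postmine characterize`, `sentiment`, `temporal` and
`correlate` expose the individual stages.

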