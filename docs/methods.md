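# Methods

## The instrument model

The toolkit models a rapid-assessment instrument with a three-level
hierarchy: *metrics* (ordinal 1–5 items scored by experts), *dimensions*
(small groups of related metrics), and *indicators* (groups of
dimensions). Output metrics measure realized performance and are
*braided*: each belongs to exactly one dimension under the
triple-bottom-line partitioning (indicators Ecology, Economics,
Community) and exactly one under the sector partitioning (Stock
Performance, Harvest Sector Performance, Post-Harvest Sector
Performance). The two views reorganize the same 68 scores; the partition
property — indicator metric sets pairwise disjoint and jointly exhaustive
under each partitioning — is enforced by the validator and asserted in
tests. Input (enabling-factor) metrics sit in a separate single hierarchy:
15 dimensions in 5 components.

The schema is data, not code. The packaged file
`src/fpikit/data/schema_default_synthetic.yaml` is the single source of
truth and the validator enforces the published totals (68 output metrics,
54 input metrics, 15 input dimensions, 5 components) so a faulty edit
fails loudly. Two caveats, both flagged in the file itself:

- The dimension structure, dimension names, and braiding rules (the
  Safety metric joining the sector Harvest dimension; the Support
  Industry metric joining Post-Harvest Processing & Support Industry)
  follow the published instrument description. Individual metric names
  and per-dimension metric counts, however, are a **synthetic
  reconstruction**: they are plausible and consistent with all published
  totals, but are not a transcription of the real instrument's item list.
- The Ecology indicator and the sector Stock Performance indicator are
  given identical metric sets (a single Stock Health dimension each).
  This identity is the natural reading of the instrument's structure but
  is a modeling choice, not a documented fact.

## Threshold scoring

Quantitatively scorable metrics use a `ThresholdRule`: four ascending
breakpoints split the measurement axis into five intervals mapped
monotonically onto levels 1–5, with an explicit ownership convention for
values landing exactly on an edge. For the packaged crew-earnings rule
(ratio r of annual crew earnings to regional average earnings) the
published band wording fixes the middle band as closed and the top band
as open: level 3 ⇔ |r−1| ≤ 0.10, level 4 ⇔ 1.10 < r ≤ 1.50, level 5 ⇔
r > 1.50. The wording does not say which band owns exactly 0.50 or 0.90;
the package assigns each edge to the band closer to the scale midpoint
(0.50 → level 2, 0.90 → level 3), a documented convention rather than a
published fact. Scoring rejects NaN and values below the rule's domain
(negative ratios).

## Aggregation

For case *c* and dimension *d* with scored (non-missing) metric levels
x_i and quality ratings q_i, the dimension score is the weighted mean
Σ w(q_i)·x_i / Σ w(q_i). Defaults:

| parameter | default | rationale |
|---|---|---|
| quality weights | A=1.0, B=0.6, C=0.3 | decreasing in scorer confidence; any uniform scheme reproduces the unweighted score exactly, and the analyses are designed so that conclusions are robust to the specific decreasing profile |
| weight for an unrated score | 1.0 | absence of a rating is not evidence of low quality |
| `indicator_method` | `dimension_mean` | dimensions are the interpretive unit, so each contributes equally regardless of metric count; `metric_mean` (flat weighted mean over all the indicator's metrics) is retained for users who prefer item-level weighting |
| `min_coverage` | 0.5 | a dimension scored on under half its metrics is flagged but still reported — partial scoring is informative by design, so nothing is dropped silently |
| color bins | red < 3 ≤ yellow < 4 ≤ green | 3 is the level below which improvement could be considered |

Missing metric levels are an explicit sentinel preserved through parsing;
they are excluded from means, never imputed. A dimension with no scored
metric is MISSING, and an indicator averages only its non-missing
dimension scores. Weighted-mean containment guarantees every aggregate
lies within [min level, max level] of its inputs.

## Rank-based comparison

Scores are ordinal, so cross-case analytics are rank-based. Rankings sort
descending with average ranks over ties (ties in display order broken by
case id for determinism). The two-sample test is the
Wilcoxon/Mann–Whitney rank-sum test:

- **Exact branch** (min(n1,n2) ≤ 10, no ties): the null distribution of
  U is built by the classic recurrence c(i,j)[u] = c(i−1,j)[u−j] +
  c(i,j−1)[u] (conditioning on the sample membership of the largest
  pooled observation); two-sided p = min(1, 2·min(P(U≤u), P(U≥u))).
  Tests verify this against an independent complete-enumeration oracle
  exhaustively for all n1, n2 ≤ 6.
- **Approximate branch** (larger samples or any ties): normal
  approximation with continuity correction and tie-corrected variance
  (via scipy). Ties in small samples also take this branch; exact
  mid-p tie handling is out of scope.

Spearman's rho is computed as the Pearson correlation of average ranks,
hence invariant to strictly monotone rescoring. Group profiles average
per-case dimension scores (or numeric quality ratings, default map A=3,
B=2, C=1 — the direction is a documented choice, configurable) within
developed/developing groups.

## The synthetic generator

`generate` draws, per case, a latent standard-normal vector over all 122
metrics with a nested block-correlation structure built by factor
construction: latent = √ρ_x·G + √(ρ_b−ρ_x)·I + √(ρ_w−ρ_b)·D + √(1−ρ_w)·ε,
where G is a global factor, I an indicator factor, D a dimension factor
and ε idiosyncratic. The constraint ρ_w ≥ ρ_b ≥ ρ_x ≥ 0 makes the implied
correlation matrix positive semi-definite by construction; violating it
raises. Output metrics block by their TBL assignment, input metrics by
the component hierarchy. Latents are discretized at fixed cutpoints into
levels 1–5; quality ratings are i.i.d. from `quality_probs`; scores are
knocked out i.i.d. at `missing_rate`. Everything is reproducible from the
seed (NumPy `default_rng`).

Defaults, chosen once as the study conditions the generator emulates:

| parameter | default | rationale |
|---|---|---|
| `n_cases` | 30 per group | a two-group collection of ~60 fisheries, the scale of the instrument's initial cross-section |
| ρ_w, ρ_b, ρ_x | 0.45, 0.20, 0.05 | metrics within a dimension cohere strongly, dimensions within an indicator moderately, and the three pillars remain correlated but clearly distinct — the "imperfectly correlated" regime the instrument is designed to expose |
| `group_shift` | calibrated | solved (Brent root-find on the closed-form expected level) so the expected ordinal developed-minus-developing gap is exactly one score level, the observed scale of the developed/developing stock contrast |
| cutpoints | −1.5, −0.5, 0.5, 1.5 | symmetric, all five levels attainable, unit latent spacing |
| `quality_probs` | A .45, B .40, C .15 | most scores confidently rated, a modest educated-guess tail |
| `missing_rate` | 0.10 | uneven information availability without degrading coverage below flagging thresholds |

Because the discretization attenuates correlations and compresses mean
shifts, recovery tests compare against what the latent parameters *imply
at the ordinal scale*: a 10⁶-draw bivariate discretization oracle for the
within-dimension Spearman rho, and the calibrated shift for the group
gap. The generator emulates correlated ordinal blocks, a group contrast
and uneven quality; it does **not** emulate scorer idiosyncrasies,
metric-specific marginals, input–output dependence, or quality ratings
correlated with levels. Passing tests therefore validate the pipeline's statistical behaviour, not
substantive claims about real fisheries.

## Monte-Carlo problem sizes and tolerances

Statistical checks run at sizes chosen so sampling noise is negligible
relative to the asserted tolerance:

- Type-I calibration of the group comparison uses 2000 null collections
  of 20 cases per group and asserts the rejection count inside the 99.9%
  binomial band around 5%.
- Group-shift recovery asserts the per-dimension gap within ±0.15 of one
  level at 200 cases per group. A single draw of that size has a
  per-dimension standard error of ~0.07–0.08, so checking ~30 dimensions
  simultaneously would fail by chance more often than not even with a
  perfectly calibrated generator; the check therefore averages gaps over
  8 independent collections (standard error ~0.03, comfortably inside
  the band without touching generator parameters).
- Statistical unit tests bound maxima over dimensions at ≥3σ of the
  relevant sampling distribution.

All stochastic tests and the hypothesis property suite are seeded or
derandomized; derived seeds stay below 2³¹.

## Numerical and design notes

- Exact U-distribution counts use float64. Arrangement totals
  C(n1+n2, n1) only approach 2⁵³ for very unbalanced samples under the
  min(n) ≤ 10 gate, where the relative rounding error (~1e-16) is
  negligible against any p-value comparison.
- Degenerate inputs: empty samples, unknown node ids, out-of-range
  scores, all-zero quality weights, non-monotone cutpoints and non-PSD
  correlation requests all raise; violations of *data* rules (a level of
  6 in a sheet) are returned as validation-report entries instead, so a
  sheet can be triaged rather than rejected wholesale.
- Collections normalize case order to case_id and score order to schema
  metric order, making write→read round-trips the identity and all
  rendered reports pure functions of their inputs.
- The CLI is a thin layer over the library: every subcommand parses,
  calls one or two library functions, and prints; nothing is computed in
  the CLI itself.

## Known limitations

- The packaged schema's metric-level content is a reconstruction (see
  above); analyses that depend on the identity of individual real
  instrument items should replace the packaged file with their own
  schema document.
- The exact rank-sum branch does not handle ties (falls back to the
  corrected approximation), and no exact confidence intervals are
  provided for rank correlations.
- Quality ratings act as weights, not variances: no uncertainty
  propagation onto aggregate scores is attempted.
- No imputation of missing levels; heavily unscored cases simply carry
  flagged, low-coverage aggregates.
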