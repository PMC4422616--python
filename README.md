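# fpikit — a Fishery Performance Indicators toolkit

Fisheries are managed for a *triple bottom line* (TBL): healthy stocks,
profitable harvest and post-harvest industries, and communities that
benefit from and support the fishery. Stock assessments cover the first
pillar; standardized data on the other two barely exist. The Fishery
Performance Indicators (FPI) instrument fills that gap with rapid expert
assessment: **68 output metrics** measuring realized TBL performance and
**54 input metrics** describing enabling conditions and management, each
scored on an ordinal 1–5 scale (5 = better performance) with an A/B/C
quality rating recording scorer confidence (A — highly confident the score
is correct; B — highly confident the true score is within one bin; C — an
educated guess).

`fpikit` is a toolkit for working with that instrument end to end. It is
aimed at analysts comparing scored fisheries, developers of rapid
assessment instruments, and anyone needing a reproducible pipeline from
ordinal expert score sheets to cross-sectional statistics:

- **schema** — the instrument as data: metrics, dimensions, indicators,
  and the dual "braiding" that assigns every output metric to one
  dimension under the TBL partitioning (Ecology / Economics / Community)
  *and* one under the sector partitioning (Stock / Harvest Sector /
  Post-Harvest Sector). A validator enforces the published totals
  (68 / 54 / 15 input dimensions / 5 components).
- **scoring** — score sheets with explicit missingness, case validation
  with coverage accounting, and threshold rules that map measured
  quantities onto the 1–5 scale (e.g. crew earnings relative to the
  regional average: level 3 ⇔ within 10% of the regional average, level 5
  ⇔ more than 50% above).
- **aggregation** — dimension score = quality-weighted mean of non-missing
  metric levels (default weights A=1.0, B=0.6, C=0.3; uniform weights
  reproduce unweighted scores exactly); indicator score = mean of its
  dimension scores; red/yellow/green binning at 3 and 4.
- **comparison** — rankings with average ranks over ties, the
  Wilcoxon/Mann–Whitney rank-sum test (exact null distribution of U for
  small untied samples, tie-corrected normal approximation otherwise),
  Spearman rank correlations, and group-mean dimension and quality
  profiles (developed vs developing fisheries).
- **synthetic** — a latent-threshold generator of correlated ordinal case
  collections with a calibrated developed/developing shift, providing
  ground truth for every downstream statistic.
- **cli / report** — the `fpi` command (`validate`, `score`, `aggregate`,
  `compare`, `simulate`, `report`) and deterministic text/HTML heatmap
  tables.

## Worked example

```python
import fpikit as fp

schema = fp.default_schema()

# threshold scoring: crew earn 30% above the regional average
rule = fp.crew_earnings_rule()
fp.score_from_thresholds(1.30, rule)        # -> 4

# a synthetic collection: 4 developed + 4 developing fisheries
cc = fp.generate(fp.SyntheticParams(n_cases=4, seed=7), schema)
table = fp.score_all(cc.cases, schema, fp.WeightingScheme.uniform(), "tbl")
print(table.frame[table.frame.node_level == "indicator"]
      .pivot(index="case_id", columns="node_id", values="score").round(2))
```

```
node_id       community  ecology  economics
case_id
syn-dev-0000       2.96     3.22       3.43
syn-dev-0001       3.54     3.12       3.71
syn-dev-0002       3.98     3.44       3.07
syn-dev-0003       4.30     3.60       3.19
syn-dvg-0000       2.81     2.29       2.21
syn-dvg-0001       1.58     1.22       2.27
syn-dvg-0002       1.27     1.75       2.51
syn-dvg-0003       2.47     1.25       1.88
```

The generator plants a one-score-level latent gap between the groups, and
the indicator scores show it. A rank-sum test of the Economics scores
between groups:

```python
econ = table.scores_of("economics")
status = {c.case_id: c.development_status for c in cc.cases}
x = [v for k, v in econ.items() if status[k] == "developed"]
y = [v for k, v in econ.items() if status[k] == "developing"]
fp.rank_sum_test(x, y)
# RankSumResult(statistic_w=26.0, u=16.0, p_two_sided=0.0286, method='exact', ...)
```

`W=26` is the rank-sum of the developed group, `U = W − n1(n1+1)/2 = 16`
(its maximum for 4 vs 4, i.e. complete separation), and the exact
two-sided p of 0.0286 is `2/C(8,4)·2` — small, but limited by n=4 per
group. At 200 cases per group the planted shift is recovered dimension by
dimension (`fp.recover_parameters(...)` reports gaps within a few
hundredths of 1.0).

The same pipeline runs from the shell:

```sh
fpi simulate --n 30 --seed 7 --out cases/
fpi aggregate --collection cases/ --partitioning tbl --out scores.csv
fpi compare --collection cases/ --node economics
fpi report --collection cases/ --sort-node ecology --format html --out report.html
```

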