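"""Dimension and indicator scores per case, unweighted or quality-weighted.

A dimension score is the (quality-)weighted mean of its non-missing metric
levels; an indicator score is, by default, the unweighted mean of its
non-missing dimension scores, so each dimension contributes equally however
many metrics it contains (``metric_mean`` flattens the hierarchy instead).
Quality weights let users discount low-confidence scores: the default
scheme weights A=1.0, B=0.6, C=0.3, and any uniform scheme reproduces the
unweighted score exactly.  Missing metrics are excluded, never imputed; a
dimension scored on less than ``min_coverage`` of its metrics is flagged
but still reported.

Scores are color-binned for reporting: red below 3 (the level below which
improvement could be considered), yellow in [3, 4), green at 4 and above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .schema import SchemaDef
from .scoring import MISSING, CaseStudy, MetricScore

__all__ = [
    "WeightingScheme",
    "ScoreTable",
    "DEFAULT_BINS",
    "dimension_score",
    "indicator_score",
    "color_bin",
    "score_all",
    "write_score_table",
]

#: Cutpoints (red|yellow, yellow|green) on the 1-5 scale.
DEFAULT_BINS = (3.0, 4.0)

SCORE_TABLE_COLUMNS = [
    "case_id",
    "partitioning",
    "node_level",
    "node_id",
    "score",
    "coverage",
    "flag",
    "color",
]


@dataclass(frozen=True)
class WeightingScheme:
    """How metric scores combine into dimension and indicator scores.

    quality_weights
        Non-negative weight per rating; a score without a rating receives
        ``missing_quality_weight``.  At least one weight must be positive.
    indicator_method
        ``"dimension_mean"`` (default): indicator = unweighted mean of its
        dimension scores.  ``"metric_mean"``: indicator = weighted mean over
        all its metrics directly.
    min_coverage
        Scored fraction of a node's metrics below which its score is
        flagged (never silently dropped).
    """

    quality_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 0.6, "C": 0.3}
    )
    indicator_method: str = "dimension_mean"
    min_coverage: float = 0.5
    missing_quality_weight: float = 1.0

    def __post_init__(self) -> None:
        ws = [float(w) for w in self.quality_weights.values()]
        if any(not math.isfinite(w) or w < 0 for w in ws):
            raise ValueError("quality weights must be finite and non-negative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one quality weight must be positive")
        if self.indicator_method not in ("dimension_mean", "metric_mean"):
            raise ValueError(f"unknown indicator_method {self.indicator_method!r}")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")

    @classmethod
    def uniform(cls, **kwargs) -> "WeightingScheme":
        """All ratings weighted equally: reproduces unweighted scores."""
        return cls(quality_weights={"A": 1.0, "B": 1.0, "C": 1.0}, **kwargs)

    def weight_of(self, score: MetricScore) -> float:
        if score.quality is None:
            return self.missing_quality_weight
        return float(self.quality_weights.get(score.quality, self.missing_quality_weight))


@dataclass
class ScoreTable:
    """Long-format aggregate scores: one row per (case, node).

    ``frame`` columns: case_id, partitioning, node_level (dimension or
    indicator), node_id, score (float or NaN for MISSING), coverage, flag,
    color.  Row order is deterministic: cases in input order, nodes in
    schema order, dimensions before indicators.
    """

    frame: pd.DataFrame
    partitioning: str
    bins: tuple[float, float] = DEFAULT_BINS

    def scores_of(self, node_id: str) -> pd.Series:
        sub = self.frame[self.frame["node_id"] == node_id]
        if sub.empty:
            raise KeyError(f"unknown node {node_id!r}")
        return sub.set_index("case_id")["score"]

    def case_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["case_id"]))


# ------------------------------------------------------------------ internals
def _weighted_mean(
    scores: Iterable[MetricScore], scheme: WeightingScheme
) -> tuple[float | None, int]:
    """(weighted mean of non-missing levels, count scored); None if empty."""
    num = 0.0
    den = 0.0
    n = 0
    for s in scores:
        if s.level is MISSING:
            continue
        w = scheme.weight_of(s)
        num += w * s.level
        den += w
        n += 1
    if n == 0 or den == 0.0:
        return MISSING, n
    return num / den, n


def _node_scores(
    case: CaseStudy, metric_ids: Sequence[str], scheme: WeightingScheme
) -> tuple[float | None, float]:
    smap = case.score_map()
    present = [smap[m] for m in metric_ids if m in smap]
    score, n_scored = _weighted_mean(present, scheme)
    coverage = n_scored / len(metric_ids) if metric_ids else 0.0
    return score, coverage


# ----------------------------------------------------------------- public API
def dimension_score(
    case: CaseStudy,
    dimension_id: str,
    schema: SchemaDef,
    scheme: WeightingScheme | None = None,
) -> float | None:
    """Quality-weighted mean level of the dimension's scored metrics.

    Returns MISSING (None) when no metric of the dimension is scored.
    Raises ``KeyError`` for an unknown dimension.
    """
    scheme = scheme or WeightingScheme.uniform()
    dim = schema.dimension_index.get(dimension_id)
    if dim is None:
        raise KeyError(f"unknown dimension {dimension_id!r}")
    metric_ids = schema.metric_ids_of(dimension_id, dim.partitioning)
    score, _ = _node_scores(case, metric_ids, scheme)
    return score


def indicator_score(
    case: CaseStudy,
    indicator_id: str,
    partitioning: str,
    schema: SchemaDef,
    scheme: WeightingScheme | None = None,
) -> float | None:
    """Indicator score under the scheme's ``indicator_method``."""
    scheme = scheme or WeightingScheme.uniform()
    if indicator_id not in schema.indicators_in(partitioning):
        raise KeyError(f"unknown indicator {indicator_id!r} in {partitioning!r}")
    if scheme.indicator_method == "metric_mean":
        metric_ids = schema.metric_ids_of(indicator_id, partitioning)
        score, _ = _node_scores(case, metric_ids, scheme)
        return score
    dim_scores = [
        dimension_score(case, d, schema, scheme)
        for d in schema.dimension_ids_of_indicator(indicator_id, partitioning)
    ]
    present = [s for s in dim_scores if s is not MISSING]
    if not present:
        return MISSING
    return sum(present) / len(present)


def color_bin(score: float, bins: tuple[float, float] = DEFAULT_BINS) -> str:
    """Bin a score into red / yellow / green for reporting."""
    if not 1.0 <= score <= 5.0:
        raise ValueError(f"score {score} outside [1, 5]")
    lo, hi = bins
    if score < lo:
        return "red"
    if score < hi:
        return "yellow"
    return "green"


def score_all(
    cases: Sequence[CaseStudy],
    schema: SchemaDef,
    scheme: WeightingScheme | None = None,
    partitioning: str = "tbl",
    bins: tuple[float, float] = DEFAULT_BINS,
) -> ScoreTable:
    """Dimension and indicator scores for every case under one partitioning.

    Deterministic: rows follow case input order; within a case, dimensions
    in schema order then indicators in schema order.
    """
    scheme = scheme or WeightingScheme.uniform()
    dims = schema.dimensions_in(partitioning)
    indicators = schema.indicators_in(partitioning)
    rows: list[tuple] = []
    for case in cases:
        for d in dims:
            metric_ids = schema.metric_ids_of(d.dimension_id, partitioning)
            score, coverage = _node_scores(case, metric_ids, scheme)
            rows.append(_row(case.case_id, partitioning, "dimension", d.dimension_id, score, coverage, scheme, bins))
        for ind in indicators:
            metric_ids = schema.metric_ids_of(ind, partitioning)
            _, coverage = _node_scores(case, metric_ids, scheme)
            score = indicator_score(case, ind, partitioning, schema, scheme)
            rows.append(_row(case.case_id, partitioning, "indicator", ind, score, coverage, scheme, bins))
    frame = pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)
    return ScoreTable(frame=frame, partitioning=partitioning, bins=bins)


def _row(case_id, partitioning, node_level, node_id, score, coverage, scheme, bins):
    flagged = score is not MISSING and coverage < scheme.min_coverage
    color = "" if score is MISSING else color_bin(score, bins)
    return (
        case_id,
        partitioning,
        node_level,
        node_id,
        float("nan") if score is MISSING else score,
        coverage,
        flagged,
        color,
    )


def write_score_table(table: ScoreTable, path) -> None:
    """Write the long-format score table as UTF-8 CSV, deterministic order."""
    table.frame.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
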