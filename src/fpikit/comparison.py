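"""Cross-fishery analytics: rankings, rank-sum tests, rank correlations.

Because metric levels are ordinal, comparisons between groups of fisheries
(developed vs developing) or between indicators use rank-based
nonparametrics.  The two-sample location test is the Wilcoxon/Mann-Whitney
rank-sum test: for small untied samples (min(n1, n2) <= 10) the two-sided
p-value is exact — computed from the full null distribution of the
Mann-Whitney U statistic over all equally likely rank assignments — and
otherwise a normal approximation with continuity correction and
tie-corrected variance is used.  Agreement between rankings is measured by
Spearman's rho, the Pearson correlation of average ranks, which is
invariant to any strictly monotone rescoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import ScoreTable, WeightingScheme, dimension_score
from .schema import SchemaDef
from .scoring import MISSING, CaseStudy

__all__ = [
    "Ranking",
    "RankSumResult",
    "rank_cases",
    "rank_sum_test",
    "rank_correlation",
    "group_dimension_means",
    "quality_profile",
    "DEFAULT_QUALITY_MAP",
]

#: Numeric map for quality ratings; A (highest confidence) maps highest.
DEFAULT_QUALITY_MAP = {"A": 3.0, "B": 2.0, "C": 1.0}

EXACT_MAX_N = 10  # exact branch when min(n1, n2) <= this and no ties


@dataclass
class Ranking:
    """Cases ordered by descending score with average ranks over ties."""

    node_id: str
    entries: list[tuple[str, float, float]]  # (case_id, score, rank)
    excluded: list[str]  # cases with MISSING score on this node
    tie_method: str = "average"

    @property
    def case_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def rank_of(self, case_id: str) -> float:
        for cid, _, rank in self.entries:
            if cid == case_id:
                return rank
        raise KeyError(case_id)


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon/Mann-Whitney two-sample test result.

    ``statistic_w`` is the rank-sum of the first sample; ``u`` the
    Mann-Whitney statistic ``W - n1(n1+1)/2``.
    """

    statistic_w: float
    u: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def rank_cases(table: ScoreTable, node_id: str) -> Ranking:
    """Rank cases on one node, descending; ties get average ranks.

    Cases with a MISSING score are excluded from the ranking and listed
    separately.  Ties in score are ordered by case_id for determinism.
    """
    scores = table.scores_of(node_id)  # raises KeyError on unknown node
    missing_mask = scores.isna()
    excluded = sorted(scores.index[missing_mask])
    present = scores[~missing_mask]
    # Stable order: descending score, then case_id.
    order = sorted(present.items(), key=lambda kv: (-kv[1], kv[0]))
    vals = np.array([v for _, v in order], dtype=float)
    ranks = stats.rankdata(-vals, method="average") if len(vals) else np.array([])
    entries = [(cid, float(v), float(r)) for (cid, v), r in zip(order, ranks)]
    return Ranking(node_id=node_id, entries=entries, excluded=list(excluded))


# ------------------------------------------------------------- rank-sum test
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as arrangement counts over u = 0..n1*n2.

    Classic recurrence: condition on the largest pooled observation.  If it
    belongs to sample 1 it exceeds all j current sample-2 members (U gains
    j); if to sample 2, U is unchanged:
    ``c(i, j)[u] = c(i-1, j)[u - j] + c(i, j-1)[u]``.
    """
    umax = n1 * n2
    # column j = 0: U identically 0 whatever i
    prev = [np.zeros(umax + 1) for _ in range(n1 + 1)]
    for i in range(n1 + 1):
        prev[i][0] = 1.0
    for j in range(1, n2 + 1):
        cur = [np.zeros(umax + 1) for _ in range(n1 + 1)]
        cur[0][0] = 1.0
        for i in range(1, n1 + 1):
            cur[i][:] = prev[i]  # largest obs from sample 2
            cur[i][j:] += cur[i - 1][:-j or None]  # largest obs from sample 1
        prev = cur
    return prev[n1]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test of x vs y.

    Exact p by the full U null distribution when ``min(n1, n2) <= 10`` and
    there are no ties across the pooled sample; otherwise the normal
    approximation with continuity correction and tie-corrected variance.
    The two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    if min(n1, n2) <= EXACT_MAX_N and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_low = counts[: ui + 1].sum() / total
        p_high = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return RankSumResult(
        statistic_w=w, u=float(u), p_two_sided=min(max(p, np.nextafter(0, 1)), 1.0),
        method=method, n1=n1, n2=n2,
    )


def rank_correlation(r1: Ranking, r2: Ranking) -> float:
    """Spearman's rho between two rankings of the same case set."""
    if set(r1.case_ids) != set(r2.case_ids):
        raise ValueError("rankings cover different case sets")
    n = len(r1.case_ids)
    if n < 2:
        raise ValueError("need at least two common cases")
    ranks2 = {cid: rank for cid, _, rank in r2.entries}
    a = np.array([rank for _, _, rank in r1.entries], dtype=float)
    b = np.array([ranks2[cid] for cid in r1.case_ids], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate ranking: all ranks tied")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------- group-level tables
def _grouping_fn(grouping) -> Callable[[CaseStudy], str]:
    if grouping is None:
        return lambda c: c.development_status
    if callable(grouping):
        return grouping
    if isinstance(grouping, Mapping):
        return lambda c: grouping[c.case_id]
    raise TypeError("grouping must be None, a callable, or a mapping")


def group_dimension_means(
    cases: Sequence[CaseStudy],
    schema: SchemaDef,
    scheme: WeightingScheme | None = None,
    grouping=None,
    partitioning: str = "tbl",
) -> pd.DataFrame:
    """Mean per-case dimension score, per dimension x group.

    ``grouping`` maps a case to its group label (default: the case's
    development status).  MISSING dimension scores are excluded from the
    means; an empty group yields a NaN column.  Raises ``ValueError`` if a
    case has no group label.
    """
    scheme = scheme or WeightingScheme.uniform()
    fn = _grouping_fn(grouping)
    dims = [d.dimension_id for d in schema.dimensions_in(partitioning)]
    records = []
    for case in cases:
        label = fn(case)
        if label is None or label == "":
            raise ValueError(f"case {case.case_id!r} has no group label")
        for d in dims:
            s = dimension_score(case, d, schema, scheme)
            records.append((d, label, np.nan if s is MISSING else s))
    frame = pd.DataFrame(records, columns=["dimension", "group", "score"])
    out = frame.pivot_table(index="dimension", columns="group", values="score", aggfunc="mean")
    return out.reindex(dims)


def quality_profile(
    cases: Sequence[CaseStudy],
    schema: SchemaDef,
    partitioning: str = "sector",
    grouping=None,
    quality_map: Mapping[str, float] = DEFAULT_QUALITY_MAP,
) -> pd.DataFrame:
    """Mean numeric quality rating, per dimension x group.

    Quality ratings map to numbers via ``quality_map`` (default A=3, B=2,
    C=1, higher = better information) and are averaged over the scored
    metrics of each dimension within each group.
    """
    fn = _grouping_fn(grouping)
    dims = [d.dimension_id for d in schema.dimensions_in(partitioning)]
    metric_dim = {
        m.metric_id: m.dimension_id_for(partitioning)
        for m in schema.metrics
        if m.dimension_id_for(partitioning) is not None
    }
    records = []
    for case in cases:
        label = fn(case)
        for s in case.scores:
            if s.quality is None or s.level is MISSING:
                continue
            d = metric_dim.get(s.metric_id)
            if d is None:
                continue
            records.append((d, label, float(quality_map[s.quality])))
    frame = pd.DataFrame(records, columns=["dimension", "group", "q"])
    if frame.empty:
        return pd.DataFrame(index=pd.Index(dims, name="dimension"))
    out = frame.pivot_table(index="dimension", columns="group", values="q", aggfunc="mean")
    return out.reindex(dims)
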