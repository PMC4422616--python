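"""Metric scores, quality ratings, case studies and threshold-based scoring.

Every metric is scored on an ordinal 1-5 scale, and every assigned score
carries a quality rating reflecting scorer confidence: ``A`` — highly
confident the score is correct; ``B`` — highly confident the true score is
within one bin; ``C`` — an educated guess.  A metric may also be left
unscored: missingness is an explicit sentinel (``MISSING``, i.e. ``None``)
that is preserved through parsing and resolved only at aggregation time,
because uneven information availability is a designed-for condition of the
instrument, not a data error.

A handful of metrics are scored mechanically from a measured quantity via a
:class:`ThresholdRule` — an ordered set of interval edges mapping the
measurement onto levels 1..5.  The packaged ``crew_earnings`` rule scores
the ratio of annual crew earnings to regional average earnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import yaml

from .schema import SchemaDef, ValidationReport

__all__ = [
    "MISSING",
    "QUALITY_RATINGS",
    "MetricScore",
    "CaseStudy",
    "ThresholdRule",
    "score_from_thresholds",
    "packaged_rules",
    "crew_earnings_rule",
    "validate_case",
]

#: Sentinel for an unscored metric level or absent quality rating.
MISSING = None

QUALITY_RATINGS = ("A", "B", "C")

VALID_LEVELS = frozenset({1, 2, 3, 4, 5})


class MetricScore(NamedTuple):
    """One scored metric: ordinal level 1..5 (or MISSING) plus quality."""

    metric_id: str
    level: int | None
    quality: str | None = None


@dataclass
class CaseStudy:
    """One fishery's metadata and metric scores at a base year."""

    case_id: str
    fishery_name: str
    country: str
    base_year: int
    development_status: str  # "developed" | "developing"
    scores: list[MetricScore] = field(default_factory=list)

    def score_map(self) -> dict[str, MetricScore]:
        return {s.metric_id: s for s in self.scores}

    def level_of(self, metric_id: str) -> int | None:
        for s in self.scores:
            if s.metric_id == metric_id:
                return s.level
        return MISSING


# ----------------------------------------------------------- threshold scoring
@dataclass(frozen=True)
class ThresholdRule:
    """Maps a measured quantity onto levels 1..5 via ordered interval edges.

    ``breakpoints`` are the four ascending edges separating levels 1|2, 2|3,
    3|4 and 4|5.  ``boundary_side[i]`` states which interval owns a value
    exactly equal to ``breakpoints[i]``: ``"lower"`` keeps it in the lower
    level, ``"upper"`` promotes it.  ``direction`` is ``"benefit"`` when a
    larger measurement earns a (weakly) higher level.
    """

    metric_id: str
    breakpoints: tuple[float, ...]
    boundary_side: tuple[str, ...]
    units: str = ""
    domain_min: float = 0.0
    direction: str = "benefit"

    def __post_init__(self) -> None:
        if len(self.breakpoints) != 4:
            raise ValueError("a 5-level rule needs exactly 4 breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.boundary_side) != len(self.breakpoints):
            raise ValueError("one boundary_side entry per breakpoint")
        if any(s not in ("lower", "upper") for s in self.boundary_side):
            raise ValueError("boundary_side entries must be 'lower' or 'upper'")


def score_from_thresholds(value: float, rule: ThresholdRule) -> int:
    """Score a measured quantity against a threshold rule.

    Deterministic, idempotent, and monotone non-decreasing in ``value`` for
    benefit-type rules.  Raises ``ValueError`` on NaN or a value below the
    rule's domain (e.g. a negative ratio).
    """
    value = float(value)
    if math.isnan(value):
        raise ValueError("cannot score NaN")
    if not math.isfinite(value):
        raise ValueError("cannot score a non-finite value")
    if value < rule.domain_min:
        raise ValueError(
            f"value {value} below the rule's domain (>= {rule.domain_min} {rule.units})"
        )
    level = 1
    for bp, side in zip(rule.breakpoints, rule.boundary_side):
        if value > bp or (value == bp and side == "upper"):
            level += 1
    return level


_rules_cache: dict[str, ThresholdRule] | None = None


def packaged_rules() -> dict[str, ThresholdRule]:
    """All threshold rules shipped with the package, keyed by rule name."""
    global _rules_cache
    if _rules_cache is None:
        ref = resources.files("fpikit.data") / "threshold_rules.yaml"
        with ref.open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        _rules_cache = {
            name: ThresholdRule(
                metric_id=entry["metric_id"],
                breakpoints=tuple(float(b) for b in entry["breakpoints"]),
                boundary_side=tuple(entry["boundary_side"]),
                units=entry.get("units", ""),
                domain_min=float(entry.get("domain_min", 0.0)),
                direction=entry.get("direction", "benefit"),
            )
            for name, entry in doc.items()
        }
    return _rules_cache


def crew_earnings_rule() -> ThresholdRule:
    """The packaged crew-earnings-to-regional-average scoring rule."""
    return packaged_rules()["crew_earnings"]


# -------------------------------------------------------------- case checking
def validate_case(case: CaseStudy, schema: SchemaDef) -> ValidationReport:
    """Check a case sheet against the schema.

    Reports unknown metric ids, out-of-range levels, quality ratings outside
    A/B/C, quality attached to a MISSING level, and duplicate entries.  The
    report carries ``coverage``: the scored (non-missing) fraction of schema
    metrics per side, ``{"output": f, "input": f}``.
    """
    report = ValidationReport()
    seen: set[str] = set()
    scored: dict[str, int] = {"output": 0, "input": 0}
    for s in case.scores:
        if s.metric_id in seen:
            report.add("duplicate_score", "metric scored more than once", s.metric_id)
            continue
        seen.add(s.metric_id)
        metric = schema.metric_index.get(s.metric_id)
        if metric is None:
            report.add("unknown_metric", "metric id not in schema", s.metric_id)
            continue
        if s.level is MISSING:
            if s.quality is not None:
                report.add("quality_on_missing", "MISSING level carries a quality rating", s.metric_id)
            continue
        if s.level not in VALID_LEVELS:
            report.add("bad_level", f"level {s.level!r} outside 1..5", s.metric_id)
            continue
        if s.quality is not None and s.quality not in QUALITY_RATINGS:
            report.add("bad_quality", f"quality {s.quality!r} not in A/B/C", s.metric_id)
        scored[metric.side] += 1
    totals = {
        "output": len(schema.output_metrics),
        "input": len(schema.input_metrics),
    }
    report.coverage = {
        side: (scored[side] / totals[side]) if totals[side] else float("nan")
        for side in ("output", "input")
    }
    return report
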