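"""Instrument structure: metrics, dimensions, indicators and partitionings.

The Fishery Performance Indicators instrument is a three-level hierarchy.
At the bottom sit 122 expert-scored metrics (1-5 ordinal levels): 68
*output* metrics measuring realized triple-bottom-line performance and 54
*input* metrics describing management regimes and enabling conditions.
Metrics roll up into dimensions, and dimensions into indicators.  Output
metrics carry **two** dimension assignments — one under the
triple-bottom-line (TBL) partitioning (Ecology / Economics / Community) and
one under the sector partitioning (Stock / Harvest Sector / Post-Harvest
Sector) — so the same scores can be read through either interpretive lens.
Input metrics have a single dimension within one of five components.

The schema is data, not code: the packaged definition file
(``data/schema_default_synthetic.yaml``) is the single source of truth, and
:func:`validate_schema` enforces the published totals (68 output metrics, 54
input metrics, 15 input dimensions over 5 components) so a faulty edit fails
loudly.  The packaged file's metric-level content is a synthetic
reconstruction of the instrument: the hierarchy, dimension names and
braiding rules follow the published description, while individual metric
names and per-dimension counts are plausible stand-ins consistent with the
published totals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MetricDef",
    "DimensionDef",
    "SchemaDef",
    "SchemaError",
    "Violation",
    "ValidationReport",
    "load_schema",
    "write_schema",
    "default_schema",
    "validate_schema",
    "metrics_of",
]

PARTITIONINGS = ("tbl", "sector", "input")

_DEFAULT_SCHEMA_RESOURCE = "schema_default_synthetic.yaml"


class SchemaError(ValueError):
    """Raised when a schema document cannot be parsed or resolved."""


@dataclass(frozen=True)
class MetricDef:
    """One instrument item.

    Output metrics carry a dimension id under each of the two output
    partitionings; input metrics carry exactly one component dimension.
    ``level_descriptors`` maps each level 1..5 to its scoring criterion text.
    """

    metric_id: str
    name: str
    side: str  # "output" | "input"
    level_descriptors: Mapping[int, str]
    tbl_dimension_id: str | None = None
    sector_dimension_id: str | None = None
    component_dimension_id: str | None = None
    notes: str = ""

    def dimension_id_for(self, partitioning: str) -> str | None:
        if partitioning == "tbl":
            return self.tbl_dimension_id
        if partitioning == "sector":
            return self.sector_dimension_id
        if partitioning == "input":
            return self.component_dimension_id
        raise ValueError(f"unknown partitioning {partitioning!r}")


@dataclass(frozen=True)
class DimensionDef:
    """A group of metrics owned by one indicator (or input component)."""

    dimension_id: str
    name: str
    parent_id: str
    partitioning: str  # "tbl" | "sector" | "input"


@dataclass
class SchemaDef:
    """The full instrument: metrics, dimensions and the three hierarchies."""

    version: str
    metrics: list[MetricDef]
    dimensions: list[DimensionDef]
    output_indicators_tbl: dict[str, str]  # indicator_id -> display name
    output_indicators_sector: dict[str, str]
    input_components: dict[str, str]

    # ------------------------------------------------------------------ caches
    def __post_init__(self) -> None:
        self._metric_index: dict[str, MetricDef] | None = None
        self._dimension_index: dict[str, DimensionDef] | None = None
        self._node_metric_ids: dict[tuple[str, str], list[str]] | None = None

    def _invalidate(self) -> None:
        self._metric_index = None
        self._dimension_index = None
        self._node_metric_ids = None

    @property
    def metric_index(self) -> dict[str, MetricDef]:
        if self._metric_index is None:
            self._metric_index = {m.metric_id: m for m in self.metrics}
        return self._metric_index

    @property
    def dimension_index(self) -> dict[str, DimensionDef]:
        if self._dimension_index is None:
            self._dimension_index = {d.dimension_id: d for d in self.dimensions}
        return self._dimension_index

    # ------------------------------------------------------------- convenience
    @property
    def output_metrics(self) -> list[MetricDef]:
        return [m for m in self.metrics if m.side == "output"]

    @property
    def input_metrics(self) -> list[MetricDef]:
        return [m for m in self.metrics if m.side == "input"]

    def metric(self, metric_id: str) -> MetricDef:
        return self.metric_index[metric_id]

    def dimension(self, dimension_id: str) -> DimensionDef:
        return self.dimension_index[dimension_id]

    def dimensions_in(self, partitioning: str) -> list[DimensionDef]:
        return [d for d in self.dimensions if d.partitioning == partitioning]

    def indicators_in(self, partitioning: str) -> dict[str, str]:
        if partitioning == "tbl":
            return self.output_indicators_tbl
        if partitioning == "sector":
            return self.output_indicators_sector
        if partitioning == "input":
            return self.input_components
        raise ValueError(f"unknown partitioning {partitioning!r}")

    def dimension_ids_of_indicator(self, indicator_id: str, partitioning: str) -> list[str]:
        return [
            d.dimension_id
            for d in self.dimensions
            if d.partitioning == partitioning and d.parent_id == indicator_id
        ]

    def metric_ids_of(self, node_id: str, partitioning: str) -> list[str]:
        """Metric ids under ``node_id`` (a dimension or an indicator/component).

        Results preserve schema metric order and contain no duplicates.
        """
        if self._node_metric_ids is None:
            self._node_metric_ids = {}
        key = (node_id, partitioning)
        if key not in self._node_metric_ids:
            self._node_metric_ids[key] = self._resolve_node(node_id, partitioning)
        return self._node_metric_ids[key]

    def _resolve_node(self, node_id: str, partitioning: str) -> list[str]:
        if partitioning not in PARTITIONINGS:
            raise KeyError(f"unknown partitioning {partitioning!r}")
        dim = self.dimension_index.get(node_id)
        if dim is not None and dim.partitioning == partitioning:
            return [
                m.metric_id
                for m in self.metrics
                if m.dimension_id_for(partitioning) == node_id
            ]
        if node_id in self.indicators_in(partitioning):
            dim_ids = set(self.dimension_ids_of_indicator(node_id, partitioning))
            return [
                m.metric_id
                for m in self.metrics
                if m.dimension_id_for(partitioning) in dim_ids
            ]
        raise KeyError(f"unknown node {node_id!r} in partitioning {partitioning!r}")


# --------------------------------------------------------------------- report
@dataclass(frozen=True)
class Violation:
    """A single schema or case-sheet rule violation (data, not an exception)."""

    code: str
    message: str
    subject: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.subject}]" if self.subject else ""
        return f"{self.code}: {self.message}{loc}"


class ValidationReport:
    """An ordered list of violations; empty means valid."""

    def __init__(self, violations: Iterable[Violation] = ()) -> None:
        self.violations: list[Violation] = list(violations)

    def add(self, code: str, message: str, subject: str | None = None) -> None:
        self.violations.append(Violation(code, message, subject))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "<ValidationReport ok>"
        body = "; ".join(str(v) for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        return f"<ValidationReport {len(self.violations)} violations: {body}{more}>"


# --------------------------------------------------------------------- loading
def _parse_metric(entry: Mapping, side: str) -> MetricDef:
    try:
        metric_id = entry["id"]
        name = entry["name"]
        levels = {int(k): str(v) for k, v in entry["levels"].items()}
    except (KeyError, TypeError, AttributeError) as exc:
        raise SchemaError(f"malformed metric entry {entry!r}") from exc
    return MetricDef(
        metric_id=metric_id,
        name=name,
        side=side,
        level_descriptors=levels,
        tbl_dimension_id=entry.get("tbl_dimension"),
        sector_dimension_id=entry.get("sector_dimension"),
        component_dimension_id=entry.get("component_dimension"),
        notes=entry.get("notes", ""),
    )


def _build_schema(doc: Mapping) -> SchemaDef:
    if not isinstance(doc, Mapping):
        raise SchemaError("schema document is not a mapping")
    indicators = doc.get("indicators", {})
    metrics = [_parse_metric(e, "output") for e in doc.get("output_metrics", [])]
    metrics += [_parse_metric(e, "input") for e in doc.get("input_metrics", [])]
    dims = []
    for e in doc.get("dimensions", []):
        try:
            dims.append(
                DimensionDef(
                    dimension_id=e["id"],
                    name=e["name"],
                    parent_id=e["parent"],
                    partitioning=e["partitioning"],
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed dimension entry {e!r}") from exc
    schema = SchemaDef(
        version=str(doc.get("version", "unversioned")),
        metrics=metrics,
        dimensions=dims,
        output_indicators_tbl=dict(indicators.get("tbl", {})),
        output_indicators_sector=dict(indicators.get("sector", {})),
        input_components=dict(doc.get("components", {})),
    )
    return schema


def load_schema(source, validate: bool = True) -> SchemaDef:
    """Load a schema definition from a YAML path, stream, or parsed mapping.

    With ``validate=True`` (the default) the loaded schema must pass
    :func:`validate_schema`; otherwise a :class:`SchemaError` listing the
    violations is raised.  Structural problems (unparseable document,
    dangling dimension references, duplicate ids) always raise.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            raise SchemaError(f"cannot load schema from {type(source).__name__}")
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"schema parse failure: {exc}") from exc
    schema = _build_schema(doc)
    structural = _structural_violations(schema)
    if structural:
        raise SchemaError("; ".join(str(v) for v in structural))
    if validate:
        report = validate_schema(schema)
        if not report.ok:
            raise SchemaError(
                "schema failed validation: " + "; ".join(str(v) for v in report)
            )
    return schema


def write_schema(schema: SchemaDef, path) -> None:
    """Serialize a schema back to the YAML layout accepted by load_schema."""
    doc: dict = {
        "version": schema.version,
        "indicators": {
            "tbl": dict(schema.output_indicators_tbl),
            "sector": dict(schema.output_indicators_sector),
        },
        "components": dict(schema.input_components),
        "dimensions": [
            {
                "id": d.dimension_id,
                "name": d.name,
                "parent": d.parent_id,
                "partitioning": d.partitioning,
            }
            for d in schema.dimensions
        ],
        "output_metrics": [],
        "input_metrics": [],
    }
    for m in schema.metrics:
        entry: dict = {
            "id": m.metric_id,
            "name": m.name,
            "levels": {int(k): v for k, v in sorted(m.level_descriptors.items())},
        }
        if m.notes:
            entry["notes"] = m.notes
        if m.side == "output":
            entry["tbl_dimension"] = m.tbl_dimension_id
            entry["sector_dimension"] = m.sector_dimension_id
            doc["output_metrics"].append(entry)
        else:
            entry["component_dimension"] = m.component_dimension_id
            doc["input_metrics"].append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


_default_schema_cache: SchemaDef | None = None


def default_schema() -> SchemaDef:
    """The packaged default instrument definition (cached)."""
    global _default_schema_cache
    if _default_schema_cache is None:
        ref = resources.files("fpikit.data") / _DEFAULT_SCHEMA_RESOURCE
        with ref.open("r", encoding="utf-8") as fh:
            _default_schema_cache = load_schema(fh)
    return _default_schema_cache


# ------------------------------------------------------------------ validation
def _structural_violations(schema: SchemaDef) -> list[Violation]:
    """Violations that make a schema unusable (always raised by load_schema)."""
    out: list[Violation] = []
    seen: set[str] = set()
    for m in schema.metrics:
        if m.metric_id in seen:
            out.append(Violation("duplicate_metric_id", "duplicate metric id", m.metric_id))
        seen.add(m.metric_id)
    dim_ids = [d.dimension_id for d in schema.dimensions]
    if len(dim_ids) != len(set(dim_ids)):
        dupes = {d for d in dim_ids if dim_ids.count(d) > 1}
        for d in sorted(dupes):
            out.append(Violation("duplicate_dimension_id", "duplicate dimension id", d))
    index = {d.dimension_id: d for d in schema.dimensions}
    for m in schema.metrics:
        for part in PARTITIONINGS:
            ref = m.dimension_id_for(part)
            if ref is not None and ref not in index:
                out.append(
                    Violation("dangling_dimension", f"metric references unknown dimension {ref!r}", m.metric_id)
                )
    for d in schema.dimensions:
        parents = schema.indicators_in(d.partitioning) if d.partitioning in PARTITIONINGS else {}
        if d.partitioning not in PARTITIONINGS:
            out.append(Violation("bad_partitioning", f"unknown partitioning {d.partitioning!r}", d.dimension_id))
        elif d.parent_id not in parents:
            out.append(
                Violation("dangling_parent", f"dimension parent {d.parent_id!r} is not a declared indicator/component", d.dimension_id)
            )
    return out


def validate_schema(schema: SchemaDef) -> ValidationReport:
    """Check every instrument invariant; violations are data, not exceptions.

    Beyond structural consistency this enforces the published totals of the
    default instrument — 68 output metrics, 54 input metrics, 15 input
    dimensions over 5 components — and the partition property (each output
    metric belongs to exactly one dimension under each output partitioning).
    """
    report = ValidationReport(_structural_violations(schema))

    if not schema.metrics:
        report.add("no_metrics", "no metrics")
        return report

    for m in schema.metrics:
        keys = set(m.level_descriptors)
        if keys != {1, 2, 3, 4, 5}:
            report.add("bad_levels", f"level descriptors keyed {sorted(keys)}, expected 1..5", m.metric_id)
        if m.side == "output":
            if m.tbl_dimension_id is None:
                report.add("missing_tbl_dimension", "output metric lacks a TBL dimension", m.metric_id)
            if m.sector_dimension_id is None:
                report.add("missing_sector_dimension", "output metric lacks a sector dimension", m.metric_id)
            if m.component_dimension_id is not None:
                report.add("unexpected_component_dimension", "output metric carries an input-component dimension", m.metric_id)
        elif m.side == "input":
            if m.component_dimension_id is None:
                report.add("missing_component_dimension", "input metric lacks a component dimension", m.metric_id)
            if m.tbl_dimension_id is not None or m.sector_dimension_id is not None:
                report.add("unexpected_output_dimension", "input metric carries an output dimension", m.metric_id)
        else:
            report.add("bad_side", f"metric side {m.side!r} not in {{output, input}}", m.metric_id)

    index = schema.dimension_index
    for m in schema.metrics:
        for part in ("tbl", "sector") if m.side == "output" else ("input",):
            ref = m.dimension_id_for(part)
            if ref is not None and ref in index and index[ref].partitioning != part:
                report.add(
                    "partitioning_mismatch",
                    f"metric assigned to dimension {ref!r} of partitioning {index[ref].partitioning!r} under {part!r}",
                    m.metric_id,
                )

    n_out = len(schema.output_metrics)
    n_in = len(schema.input_metrics)
    if n_out != 68:
        report.add("output_metric_count", f"output metric count {n_out} != 68")
    if n_in != 54:
        report.add("input_metric_count", f"input metric count {n_in} != 54")
    n_input_dims = len(schema.dimensions_in("input"))
    if n_input_dims != 15:
        report.add("input_dimension_count", f"input dimension count {n_input_dims} != 15")
    if len(schema.input_components) != 5:
        report.add("component_count", f"input component count {len(schema.input_components)} != 5")

    # Partition property: each output partitioning's indicator metric sets are
    # pairwise disjoint and jointly exhaust the output metrics.
    out_ids = {m.metric_id for m in schema.output_metrics}
    for part in ("tbl", "sector"):
        covered: list[str] = []
        for ind in schema.indicators_in(part):
            try:
                covered.extend(schema._resolve_node(ind, part))
            except KeyError:
                report.add("empty_indicator", f"indicator {ind!r} resolves no metrics", ind)
        if len(covered) != len(set(covered)):
            report.add("overlapping_indicators", f"{part} indicator metric sets overlap")
        if set(covered) != out_ids:
            missing = sorted(out_ids - set(covered))
            if missing:
                report.add(
                    "uncovered_metrics",
                    f"{part} indicators do not cover output metrics: {', '.join(missing[:5])}",
                )
    return report


def metrics_of(schema: SchemaDef, node_id: str, partitioning: str) -> list[MetricDef]:
    """Transitive metric set of a dimension, indicator, or input component.

    For an indicator this is the concatenation of its dimensions' metric
    lists (schema order, no duplicates).  Raises ``KeyError`` for an unknown
    node or partitioning.
    """
    return [schema.metric(mid) for mid in schema.metric_ids_of(node_id, partitioning)]
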