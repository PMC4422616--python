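"""Reading and writing case studies and multi-case collections.

Two plain-text layouts are supported, both UTF-8 with ``.`` decimals and
``NA`` as the missing token:

* a per-case *score sheet* (``metric_id,level,quality`` CSV) with a YAML
  metadata sidecar (case id, fishery name, country, base year, development
  status) — the shape in which hand-scored worksheets arrive; and
* a *collection directory* holding ``scores.csv`` in long format
  (``case_id,metric_id,level,quality``) plus ``cases.yaml`` with per-case
  metadata, provenance notes, and the schema version the scores refer to.

Writes are deterministic: cases ordered by case_id, rows within a case in
schema metric order, so write-read round-trips are the identity on
validated collections.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .schema import SchemaDef
from .scoring import MISSING, CaseStudy, MetricScore, validate_case

__all__ = [
    "CaseCollection",
    "CaseIOError",
    "read_case",
    "write_case",
    "read_collection",
    "write_collection",
]

NA_TOKEN = "NA"


class CaseIOError(ValueError):
    """Raised on unparseable or (in strict mode) invalid case files."""


@dataclass
class CaseCollection:
    """A set of scored fisheries analyzed cross-sectionally."""

    cases: list[CaseStudy]
    schema_version: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CaseIOError(f"duplicate case ids: {', '.join(dupes)}")
        self.cases.sort(key=lambda c: c.case_id)

    def case(self, case_id: str) -> CaseStudy:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


# ------------------------------------------------------------------ per case
def _parse_level(token: str, where: str) -> int | None:
    token = token.strip()
    if token == NA_TOKEN or token == "":
        return MISSING
    try:
        return int(token)
    except ValueError as exc:
        raise CaseIOError(f"unparseable level {token!r} at {where}") from exc


def _parse_quality(token: str) -> str | None:
    token = token.strip()
    return None if token in (NA_TOKEN, "") else token


def _metadata_from(doc: dict, source: str) -> dict:
    required = ("case_id", "fishery_name", "country", "base_year", "development_status")
    missing = [k for k in required if k not in doc]
    if missing:
        raise CaseIOError(f"{source}: missing metadata keys {', '.join(missing)}")
    return {k: doc[k] for k in required}


def read_case(
    sheet_path, metadata_path, schema: SchemaDef, strict: bool = True
) -> CaseStudy:
    """Read one score sheet plus metadata sidecar into a validated CaseStudy.

    In strict mode any validation violation (unknown metric, bad level,
    duplicate row) raises :class:`CaseIOError`; in lenient mode violations
    are emitted as warnings and the case is returned as parsed — unknown
    metrics are reported either way, never silently dropped.
    """
    try:
        meta_doc = yaml.safe_load(Path(metadata_path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise CaseIOError(f"cannot parse metadata {metadata_path}: {exc}") from exc
    meta = _metadata_from(meta_doc or {}, str(metadata_path))

    scores: list[MetricScore] = []
    with open(sheet_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["metric_id", "level", "quality"]:
            raise CaseIOError(f"{sheet_path}: expected header metric_id,level,quality")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise CaseIOError(f"{sheet_path}:{lineno}: expected 3 columns")
            level = _parse_level(row[1], f"{sheet_path}:{lineno}")
            quality = _parse_quality(row[2])
            if level is MISSING:
                quality = None  # a MISSING level carries no quality rating
            scores.append(MetricScore(row[0].strip(), level, quality))

    case = CaseStudy(
        case_id=str(meta["case_id"]),
        fishery_name=str(meta["fishery_name"]),
        country=str(meta["country"]),
        base_year=int(meta["base_year"]),
        development_status=str(meta["development_status"]),
        scores=scores,
    )
    report = validate_case(case, schema)
    if not report.ok:
        summary = "; ".join(str(v) for v in report)
        if strict:
            raise CaseIOError(f"{sheet_path}: validation failed: {summary}")
        warnings.warn(f"{sheet_path}: {summary}", stacklevel=2)
    return case


def write_case(case: CaseStudy, sheet_path, metadata_path, schema: SchemaDef | None = None) -> None:
    """Write one case as sheet + sidecar; rows in schema metric order."""
    scores = _ordered_scores(case, schema)
    with open(sheet_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["metric_id", "level", "quality"])
        for s in scores:
            writer.writerow(_score_row(s))
    meta = {
        "case_id": case.case_id,
        "fishery_name": case.fishery_name,
        "country": case.country,
        "base_year": case.base_year,
        "development_status": case.development_status,
    }
    with open(metadata_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False, allow_unicode=True)


def _score_row(s: MetricScore) -> list[str]:
    return [
        s.metric_id,
        NA_TOKEN if s.level is MISSING else str(s.level),
        NA_TOKEN if s.quality is None else s.quality,
    ]


def _ordered_scores(case: CaseStudy, schema: SchemaDef | None) -> list[MetricScore]:
    if schema is None:
        return list(case.scores)
    order = {m.metric_id: i for i, m in enumerate(schema.metrics)}
    return sorted(case.scores, key=lambda s: (order.get(s.metric_id, len(order)), s.metric_id))


# ---------------------------------------------------------------- collections
def write_collection(collection: CaseCollection, directory, schema: SchemaDef | None = None) -> None:
    """Write ``scores.csv`` + ``cases.yaml`` under ``directory``.

    Byte-stable: cases sorted by case_id, scores in schema metric order,
    locale-independent formatting.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "scores.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["case_id", "metric_id", "level", "quality"])
        for case in collection.cases:
            for s in _ordered_scores(case, schema):
                writer.writerow([case.case_id] + _score_row(s))
    meta = {
        "schema_version": collection.schema_version,
        "provenance": collection.provenance,
        "cases": [
            {
                "case_id": c.case_id,
                "fishery_name": c.fishery_name,
                "country": c.country,
                "base_year": c.base_year,
                "development_status": c.development_status,
            }
            for c in collection.cases
        ],
    }
    with open(directory / "cases.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False, allow_unicode=True)


def read_collection(directory, schema: SchemaDef, strict: bool = True) -> CaseCollection:
    """Read a collection directory; warns on a schema-version mismatch."""
    directory = Path(directory)
    meta_path = directory / "cases.yaml"
    scores_path = directory / "scores.csv"
    if not meta_path.exists() or not scores_path.exists():
        raise CaseIOError(f"{directory}: not a collection (needs cases.yaml and scores.csv)")
    try:
        meta = yaml.safe_load(meta_path.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise CaseIOError(f"cannot parse {meta_path}: {exc}") from exc

    version = str(meta.get("schema_version", ""))
    if version and version != schema.version:
        warnings.warn(
            f"collection references schema version {version!r}, "
            f"loaded schema is {schema.version!r}",
            stacklevel=2,
        )

    by_case: dict[str, list[MetricScore]] = {}
    with open(scores_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != ["case_id", "metric_id", "level", "quality"]:
            raise CaseIOError(f"{scores_path}: expected header case_id,metric_id,level,quality")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                raise CaseIOError(f"{scores_path}:{lineno}: expected 4 columns")
            level = _parse_level(row[2], f"{scores_path}:{lineno}")
            quality = None if level is MISSING else _parse_quality(row[3])
            by_case.setdefault(row[0].strip(), []).append(
                MetricScore(row[1].strip(), level, quality)
            )

    cases = []
    for entry in meta.get("cases", []):
        m = _metadata_from(entry, str(meta_path))
        case = CaseStudy(
            case_id=str(m["case_id"]),
            fishery_name=str(m["fishery_name"]),
            country=str(m["country"]),
            base_year=int(m["base_year"]),
            development_status=str(m["development_status"]),
            scores=by_case.pop(str(m["case_id"]), []),
        )
        report = validate_case(case, schema)
        if not report.ok:
            summary = "; ".join(str(v) for v in report)
            if strict:
                raise CaseIOError(f"case {case.case_id!r}: validation failed: {summary}")
            warnings.warn(f"case {case.case_id!r}: {summary}", stacklevel=2)
        cases.append(case)
    if by_case:
        orphans = ", ".join(sorted(by_case))
        raise CaseIOError(f"{scores_path}: scores for undeclared cases: {orphans}")
    return CaseCollection(
        cases=cases,
        schema_version=version,
        provenance=str(meta.get("provenance", "")),
    )
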