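"""Template file I/O: YAML (canonical) and JSON (equivalent) documents.

Document layout (schema version 1)::

    schema_version: 1
    name: ...
    currency_year: 2005
    notes: ...
    params: {population: ..., n_provinces: ..., n_districts: ..., n_points_of_entry: ...}
    lines:
      - id: ...
        category: ...
        indicator: ...
        level: central | intermediate | peripheral | community | point_of_entry
        input_class: physical_infrastructure | human_capabilities | tools_processes
        driver: {kind: ..., ratio: ..., offset: ...}   # ratio omitted for constant
        unit_fixed: <integer dollars>
        unit_operating: {low: <int>, high: <int>}
        note: ...

Money is serialised as plain integers (no separators or currency symbols).
Writing is canonical: fixed key order, stable across runs, so rewriting an
unchanged template is byte-identical. The three failure modes of reading —
parse failure, unsupported schema version, validation failure — raise
distinguishable exceptions, and validation problems are reported all
together, not one at a time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .model import (
    CostLine,
    CountryParams,
    CountryTemplate,
    DriverKind,
    InputClass,
    MoneyRange,
    ScalingDriver,
    SystemLevel,
    Violation,
    validate_template,
)

__all__ = [
    "SCHEMA_VERSION",
    "TemplateIOError",
    "TemplateParseError",
    "SchemaVersionError",
    "TemplateValidationError",
    "read_template",
    "write_template",
    "template_to_document",
    "template_from_document",
]

SCHEMA_VERSION = 1


class TemplateIOError(Exception):
    """Base class for template file errors."""


class TemplateParseError(TemplateIOError):
    """The file is not well-formed YAML/JSON or lacks the document structure."""


class SchemaVersionError(TemplateIOError):
    """The document declares a schema version this library does not support."""


class TemplateValidationError(TemplateIOError):
    """The document parsed but the template breaks invariants.

    Carries the full list of violations; the message lists all of them.
    """

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "\n".join(f"  - {v}" for v in violations)
        super().__init__(f"template failed validation with "
                         f"{len(violations)} violation(s):\n{lines}")


def _as_int(value: Any, default: int = 0) -> Any:
    # Leave non-integers untouched; validate_template reports them.
    return value if value is not None else default


def template_from_document(doc: Any, *, source: str = "<document>") -> CountryTemplate:
    """Build a template from a parsed document, validating structure and content."""
    if not isinstance(doc, dict):
        raise TemplateParseError(f"{source}: document root must be a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{source}: unsupported schema version {version!r} "
            f"(this library reads version {SCHEMA_VERSION})")

    raw_params = doc.get("params") or {}
    if not isinstance(raw_params, dict):
        raise TemplateParseError(f"{source}: 'params' must be a mapping")
    unknown = set(raw_params) - set(CountryParams.FIELDS)
    if unknown:
        raise TemplateParseError(f"{source}: unknown params {sorted(unknown)}")
    params = CountryParams(**{k: raw_params[k] for k in CountryParams.FIELDS
                              if k in raw_params})

    raw_lines = doc.get("lines", [])
    if not isinstance(raw_lines, list):
        raise TemplateParseError(f"{source}: 'lines' must be a list")
    lines: list[CostLine] = []
    for i, raw in enumerate(raw_lines):
        if not isinstance(raw, dict):
            raise TemplateParseError(f"{source}: line {i} must be a mapping")
        raw_driver = raw.get("driver") or {}
        if not isinstance(raw_driver, dict):
            raise TemplateParseError(f"{source}: line {i} 'driver' must be a mapping")
        raw_op = raw.get("unit_operating") or {}
        if not isinstance(raw_op, dict):
            raise TemplateParseError(
                f"{source}: line {i} 'unit_operating' must be a mapping")
        lines.append(CostLine(
            id=str(raw.get("id", f"<line {i}>")),
            category=str(raw.get("category", "")),
            indicator=str(raw.get("indicator", "")),
            level=raw.get("level", ""),
            input_class=raw.get("input_class", ""),
            driver=ScalingDriver(kind=raw_driver.get("kind", ""),
                                 ratio=raw_driver.get("ratio"),
                                 offset=_as_int(raw_driver.get("offset"))),
            unit_fixed=_as_int(raw.get("unit_fixed")),
            unit_operating=MoneyRange(_as_int(raw_op.get("low")),
                                      _as_int(raw_op.get("high"))),
            note=str(raw.get("note", "")),
        ))

    template = CountryTemplate(
        params=params,
        lines=tuple(lines),
        name=str(doc.get("name", "")),
        currency_year=_as_int(doc.get("currency_year"), 2005),
        notes=str(doc.get("notes", "")),
    )
    violations = validate_template(template)
    if violations:
        raise TemplateValidationError(violations)
    return template


def _enum_str(value: Any) -> str:
    return value.value if hasattr(value, "value") else str(value)


def template_to_document(template: CountryTemplate) -> dict:
    """Canonical document form: fixed key order, enums as strings."""
    lines = []
    for ln in template.lines:
        driver: dict[str, Any] = {"kind": _enum_str(ln.driver.kind)}
        if ln.driver.ratio is not None:
            driver["ratio"] = ln.driver.ratio
        driver["offset"] = ln.driver.offset
        entry: dict[str, Any] = {
            "id": ln.id,
            "category": ln.category,
            "indicator": _enum_str(ln.indicator),
            "level": _enum_str(ln.level),
            "input_class": _enum_str(ln.input_class),
            "driver": driver,
            "unit_fixed": ln.unit_fixed,
            "unit_operating": {"low": ln.unit_operating.low,
                               "high": ln.unit_operating.high},
        }
        if ln.note:
            entry["note"] = ln.note
        lines.append(entry)
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "name": template.name,
        "currency_year": template.currency_year,
    }
    if template.notes:
        doc["notes"] = template.notes
    doc["params"] = {k: getattr(template.params, k) for k in CountryParams.FIELDS}
    doc["lines"] = lines
    return doc


def read_template(path: str | Path) -> CountryTemplate:
    """Read and validate a template file (YAML, or JSON by extension).

    Raises :class:`TemplateParseError`, :class:`SchemaVersionError` or
    :class:`TemplateValidationError`; the last carries every violation found.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise TemplateParseError(f"{path}: could not parse: {exc}") from exc
    return template_from_document(doc, source=str(path))


def write_template(template: CountryTemplate, path: str | Path) -> None:
    """Write a validated template in canonical form (YAML, or JSON by extension).

    Key order and formatting are fixed, so writing the same template twice
    produces byte-identical files.
    """
    violations = validate_template(template)
    if violations:
        raise TemplateValidationError(violations)
    path = Path(path)
    doc = template_to_document(template)
    if path.suffix.lower() == ".json":
        text = json.dumps(doc, indent=2) + "\n"
    else:
        text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=88)
    path.write_text(text, encoding="utf-8")
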