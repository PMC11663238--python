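"""Readers and writers for the annotation file formats.

Two interchangeable on-disk representations are supported:

* **CSV (long format)** — one row per nonzero error cell with columns
  ``image_id, model, prompt, annotator, person_count, region, error_type,
  severity, count``, plus one companion row per region carrying the
  expected part count (``error_type="_expected"``, ``severity="_"``).
* **JSON** — an array of per-annotation objects
  ``{image_id, model, prompt, annotator, person_count,
  expected: {region: m}, errors: [{region, type, severity, count}]}``.

Writing is deterministic (stable ordering) so files are diffable; reading
validates and raises :class:`AnnotationSchemaError` on any violation.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal

from .types import (
    REGIONS,
    AnnotationSchemaError,
    AnnotationSet,
    BodyRegion,
    ErrorRecord,
    ErrorType,
    ImageAnnotation,
    RegionExpectation,
    Severity,
    validate,
)

CSV_COLUMNS = [
    "image_id",
    "model",
    "prompt",
    "annotator",
    "person_count",
    "region",
    "error_type",
    "severity",
    "count",
]

EXPECTED_MARKER = "_expected"
EXPECTED_SEVERITY_MARKER = "_"

Format = Literal["csv", "json"]


def _parse_enum(enum_cls, raw: str, what: str, where: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise AnnotationSchemaError(
            f"{where}: unknown {what} {raw!r} (allowed: {allowed})"
        ) from None


def _parse_int(raw, what: str, where: str) -> int:
    try:
        value = int(str(raw))
    except (TypeError, ValueError):
        raise AnnotationSchemaError(f"{where}: {what} must be an integer, got {raw!r}") from None
    return value


def _infer_format(path: Path, format: Format | None) -> Format:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format='csv'|'json'")


def read_annotations(path: str | Path, format: Format | None = None) -> AnnotationSet:
    """Read and validate an annotation file.

    Missing error cells are treated as count zero. Any schema or invariant
    violation raises :class:`AnnotationSchemaError` naming the offending
    row or field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        aset = _read_csv(path)
    else:
        aset = _read_json(path)
    problems = validate(aset)
    if problems:
        raise AnnotationSchemaError(
            f"{path}: {len(problems)} validation error(s):\n" + "\n".join(problems)
        )
    return aset


def write_annotations(
    annotation_set: AnnotationSet, path: str | Path, format: Format | None = None
) -> None:
    """Write a set to disk; two writes of the same set are byte-identical."""
    path = Path(path)
    fmt = _infer_format(path, format)
    ordered = annotation_set.sorted()
    if fmt == "csv":
        _write_csv(ordered, path)
    else:
        _write_json(ordered, path)


# ---------------------------------------------------------------------------
# CSV


def _read_csv(path: Path) -> AnnotationSet:
    builders: dict[tuple[str, str], dict] = {}
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise AnnotationSchemaError(f"{path}: empty file, header row required")
            missing = set(CSV_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise AnnotationSchemaError(
                    f"{path}: missing required column(s): {', '.join(sorted(missing))}"
                )
            for lineno, row in enumerate(reader, start=2):
                _ingest_csv_row(builders, row, f"{path} line {lineno}")
    except (OSError, UnicodeDecodeError, csv.Error) as exc:
        raise AnnotationSchemaError(f"{path}: unreadable CSV ({exc})") from exc
    return _assemble(builders)


def _ingest_csv_row(builders: dict, row: dict, where: str) -> None:
    image_id = row.get("image_id") or ""
    annotator = row.get("annotator") or ""
    if not image_id or not annotator:
        raise AnnotationSchemaError(f"{where}: image_id and annotator are required")
    key = (image_id, annotator)
    b = builders.setdefault(
        key,
        {
            "model": row.get("model") or "",
            "prompt": row.get("prompt") or "",
            "person_count": _parse_int(row.get("person_count"), "person_count", where),
            "expected": {},
            "errors": {},
        },
    )
    for field_name in ("model", "prompt"):
        if (row.get(field_name) or "") != b[field_name]:
            raise AnnotationSchemaError(
                f"{where}: inconsistent {field_name} for image {image_id!r} "
                f"annotator {annotator!r}"
            )
    if _parse_int(row.get("person_count"), "person_count", where) != b["person_count"]:
        raise AnnotationSchemaError(
            f"{where}: inconsistent person_count for image {image_id!r} "
            f"annotator {annotator!r}"
        )

    region = _parse_enum(BodyRegion, row.get("region") or "", "region", where)
    count = _parse_int(row.get("count"), "count", where)
    if row.get("error_type") == EXPECTED_MARKER:
        if row.get("severity") != EXPECTED_SEVERITY_MARKER:
            raise AnnotationSchemaError(
                f"{where}: expectation rows must use severity {EXPECTED_SEVERITY_MARKER!r}"
            )
        if region in b["expected"]:
            raise AnnotationSchemaError(
                f"{where}: duplicate expectation row for region {region.value}"
            )
        b["expected"][region] = count
    else:
        etype = _parse_enum(ErrorType, row.get("error_type") or "", "error_type", where)
        severity = _parse_enum(Severity, row.get("severity") or "", "severity", where)
        cell = (region, etype, severity)
        if cell in b["errors"]:
            raise AnnotationSchemaError(
                f"{where}: duplicate error row for "
                f"({region.value}, {etype.value}, {severity.value})"
            )
        b["errors"][cell] = count


def _assemble(builders: dict) -> AnnotationSet:
    annotations = []
    for (image_id, annotator), b in builders.items():
        for region in REGIONS:
            b["expected"].setdefault(region, 0)
        try:
            annotations.append(
                ImageAnnotation(
                    image_id=image_id,
                    model=b["model"],
                    prompt=b["prompt"],
                    annotator=annotator,
                    person_count=b["person_count"],
                    expectations=[
                        RegionExpectation(region=r, expected_count=b["expected"][r])
                        for r in REGIONS
                    ],
                    errors=[
                        ErrorRecord(region=r, error_type=t, severity=s, count=c)
                        for (r, t, s), c in b["errors"].items()
                        if c != 0
                    ],
                )
            )
        except AnnotationSchemaError as exc:
            raise AnnotationSchemaError(
                f"image {image_id!r} annotator {annotator!r}: {exc}"
            ) from None
    return AnnotationSet(annotations).sorted()


def _write_csv(ordered: AnnotationSet, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for a in ordered:
            base = [a.image_id, a.model, a.prompt, a.annotator, a.person_count]
            for exp in a.expectations:
                writer.writerow(
                    base
                    + [exp.region.value, EXPECTED_MARKER, EXPECTED_SEVERITY_MARKER, exp.expected_count]
                )
            for rec in a.errors:
                writer.writerow(
                    base
                    + [rec.region.value, rec.error_type.value, rec.severity.value, rec.count]
                )


# ---------------------------------------------------------------------------
# JSON


def _read_json(path: Path) -> AnnotationSet:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise AnnotationSchemaError(f"{path}: unreadable JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise AnnotationSchemaError(f"{path}: top level must be an array of annotations")

    builders: dict[tuple[str, str], dict] = {}
    for idx, obj in enumerate(payload):
        where = f"{path} item {idx}"
        if not isinstance(obj, dict):
            raise AnnotationSchemaError(f"{where}: annotation must be an object")
        image_id = str(obj.get("image_id") or "")
        annotator = str(obj.get("annotator") or "")
        if not image_id or not annotator:
            raise AnnotationSchemaError(f"{where}: image_id and annotator are required")
        key = (image_id, annotator)
        if key in builders:
            raise AnnotationSchemaError(
                f"{where}: duplicate annotation for image {image_id!r} "
                f"annotator {annotator!r}"
            )
        expected_raw = obj.get("expected")
        if not isinstance(expected_raw, dict):
            raise AnnotationSchemaError(f"{where}: 'expected' must be an object")
        expected = {
            _parse_enum(BodyRegion, k, "region", where): _parse_int(
                v, f"expected count for {k!r}", where
            )
            for k, v in expected_raw.items()
        }
        errors: dict = {}
        for rec in obj.get("errors", []):
            if not isinstance(rec, dict):
                raise AnnotationSchemaError(f"{where}: error entries must be objects")
            cell = (
                _parse_enum(BodyRegion, str(rec.get("region")), "region", where),
                _parse_enum(ErrorType, str(rec.get("type")), "error_type", where),
                _parse_enum(Severity, str(rec.get("severity")), "severity", where),
            )
            if cell in errors:
                raise AnnotationSchemaError(
                    f"{where}: duplicate error entry for "
                    f"({cell[0].value}, {cell[1].value}, {cell[2].value})"
                )
            errors[cell] = _parse_int(rec.get("count"), "count", where)
        builders[key] = {
            "model": str(obj.get("model") or ""),
            "prompt": str(obj.get("prompt") or ""),
            "person_count": _parse_int(obj.get("person_count"), "person_count", where),
            "expected": expected,
            "errors": errors,
        }
    return _assemble(builders)


def _write_json(ordered: AnnotationSet, path: Path) -> None:
    payload = []
    for a in ordered:
        payload.append(
            {
                "image_id": a.image_id,
                "model": a.model,
                "prompt": a.prompt,
                "annotator": a.annotator,
                "person_count": a.person_count,
                "expected": {e.region.value: e.expected_count for e in a.expectations},
                "errors": [
                    {
                        "region": r.region.value,
                        "type": r.error_type.value,
                        "severity": r.severity.value,
                        "count": r.count,
                    }
                    for r in a.errors
                ],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
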