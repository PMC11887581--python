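"""Bulk input handling: FHIR resources, CSV files, deduplication, reports.

Postcoordinated expressions arrive embedded in FHIR R4 terminology-bearing
resources (Questionnaire item trees, ValueSet compose/expansion, ConceptMap
groups) or as CSV files. A code is treated as postcoordinated iff its coding
system is SNOMED CT and the code contains at least one Compositional-Grammar
structural character — bare precoordinated SCTIDs are skipped, since the
tool validates expressions, not whole value sets.

Resources are read as plain JSON; extraction is non-destructive and every
occurrence records a JSON-pointer (or CSV row) origin back into the source
document.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import mrcm, scg
from .corrections import CorrectionReport, apply_and_revalidate, build_report
from .terminology import TerminologyGraph
from .validator import CATEGORY_LABELS, IssueCode

SNOMED_SYSTEM = "http://snomed.info/sct"
STRUCTURAL_CHARS = ":{=+("


class UnsupportedResourceError(Exception):
    def __init__(self, resource_type):
        self.resource_type = resource_type
        super().__init__(f"unsupported FHIR resourceType: {resource_type!r}")


@dataclass(frozen=True)
class PceOccurrence:
    expression: str
    origin: str  # file path + JSON pointer, or CSV row number
    resource_type: str  # Questionnaire, ValueSet, ConceptMap, CSV, inline


@dataclass(frozen=True)
class BatchReport:
    total_occurrences: int
    unique_expressions: int
    per_expression: tuple[CorrectionReport, ...]
    per_category_frequency: dict[str, int]


def is_postcoordinated(code: str) -> bool:
    return any(ch in code for ch in STRUCTURAL_CHARS)


def _coding_occurrence(coding: dict, pointer: str, resource_type: str, prefix: str):
    if not isinstance(coding, dict):
        return None
    if coding.get("system") != SNOMED_SYSTEM:
        return None
    code = coding.get("code")
    if not isinstance(code, str) or not is_postcoordinated(code):
        return None
    return PceOccurrence(code, f"{prefix}{pointer}/code", resource_type)


def _questionnaire_items(items, pointer, resource_type, prefix, out):
    for i, item in enumerate(items or []):
        base = f"{pointer}/{i}"
        for j, coding in enumerate(item.get("code", [])):
            occ = _coding_occurrence(coding, f"{base}/code/{j}", resource_type, prefix)
            if occ:
                out.append(occ)
        for j, option in enumerate(item.get("answerOption", [])):
            coding = option.get("valueCoding")
            if coding:
                occ = _coding_occurrence(
                    coding, f"{base}/answerOption/{j}/valueCoding", resource_type, prefix
                )
                if occ:
                    out.append(occ)
        for j, initial in enumerate(item.get("initial", [])):
            coding = initial.get("valueCoding")
            if coding:
                occ = _coding_occurrence(
                    coding, f"{base}/initial/{j}/valueCoding", resource_type, prefix
                )
                if occ:
                    out.append(occ)
        _questionnaire_items(item.get("item"), f"{base}/item", resource_type, prefix, out)


def _valueset_contains(entries, pointer, prefix, out):
    for i, entry in enumerate(entries or []):
        base = f"{pointer}/{i}"
        occ = _coding_occurrence(entry, base, "ValueSet", prefix)
        if occ:
            out.append(occ)
        _valueset_contains(entry.get("contains"), f"{base}/contains", prefix, out)


def extract_pces(document: dict, origin_prefix: str = "") -> list[PceOccurrence]:
    """Every postcoordinated SNOMED CT code in a supported FHIR resource.

    Questionnaire traversal covers nested item trees, item codes, answer
    options, and initial values; ValueSet covers compose.include concepts and
    (recursive) expansion.contains; ConceptMap covers group source and target
    codes.
    """
    resource_type = document.get("resourceType")
    out: list[PceOccurrence] = []
    if resource_type == "Questionnaire":
        _questionnaire_items(document.get("item"), "/item", resource_type, origin_prefix, out)
    elif resource_type == "ValueSet":
        compose = document.get("compose", {})
        for i, include in enumerate(compose.get("include", [])):
            system = include.get("system")
            for j, concept in enumerate(include.get("concept", [])):
                coding = {"system": system, "code": concept.get("code")}
                occ = _coding_occurrence(
                    coding,
                    f"/compose/include/{i}/concept/{j}",
                    resource_type,
                    origin_prefix,
                )
                if occ:
                    out.append(occ)
        expansion = document.get("expansion", {})
        _valueset_contains(
            expansion.get("contains"), "/expansion/contains", origin_prefix, out
        )
    elif resource_type == "ConceptMap":
        for i, group in enumerate(document.get("group", [])):
            source_system = group.get("source")
            target_system = group.get("target")
            for j, element in enumerate(group.get("element", [])):
                coding = {"system": source_system, "code": element.get("code")}
                occ = _coding_occurrence(
                    coding, f"/group/{i}/element/{j}", resource_type, origin_prefix
                )
                if occ:
                    out.append(occ)
                for k, target in enumerate(element.get("target", [])):
                    coding = {"system": target_system, "code": target.get("code")}
                    occ = _coding_occurrence(
                        coding,
                        f"/group/{i}/element/{j}/target/{k}",
                        resource_type,
                        origin_prefix,
                    )
                    if occ:
                        out.append(occ)
    else:
        raise UnsupportedResourceError(resource_type)
    return out


def read_expressions_csv(path: str | Path) -> list[PceOccurrence]:
    """One expression per row, first column; optional ``expression`` header."""
    out = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        for row_number, row in enumerate(reader, start=1):
            if not row or not row[0].strip():
                continue
            if row_number == 1 and row[0].strip().lower() == "expression":
                continue
            out.append(
                PceOccurrence(row[0].strip(), f"{path}:row {row_number}", "CSV")
            )
    return out


def read_expressions_file(path: str | Path) -> list[PceOccurrence]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as handle:
            document = json.load(handle)
        return extract_pces(document, origin_prefix=str(path))
    return read_expressions_csv(path)


def dedupe(occurrences: list[PceOccurrence]) -> dict[str, list[PceOccurrence]]:
    """Group occurrences under the canonical serialization of their
    expression; unparseable expressions are keyed by their raw text."""
    out: dict[str, list[PceOccurrence]] = {}
    for occ in occurrences:
        parsed = scg.parse_expression(occ.expression)
        key = (
            scg.serialize_canonical(parsed)
            if isinstance(parsed, scg.Expression)
            else occ.expression
        )
        out.setdefault(key, []).append(occ)
    return out


def validate_batch(
    occurrences: list[PceOccurrence],
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
    apply_suggestions: bool = False,
) -> BatchReport:
    """Validate the unique expressions of a batch and tally error categories."""
    grouped = dedupe(occurrences)
    reports = []
    frequency: dict[str, int] = {}
    for key in sorted(grouped):
        representative = grouped[key][0].expression
        report = build_report(representative, graph, model)
        if apply_suggestions and report.issues:
            report = apply_and_revalidate(report, graph, model)
        reports.append(report)
        for issue, _suggestions in report.issues:
            frequency[issue.code.value] = frequency.get(issue.code.value, 0) + 1
    return BatchReport(
        total_occurrences=len(occurrences),
        unique_expressions=len(grouped),
        per_expression=tuple(reports),
        per_category_frequency=frequency,
    )


# ---------------------------------------------------------------------------
# report serialization

def _issue_to_dict(issue) -> dict:
    offending = issue.offending
    if isinstance(offending, scg.ConceptRef):
        offending = {"id": offending.id, "term": offending.term}
    return {
        "category": issue.code.value,
        "categoryLabel": CATEGORY_LABELS[issue.code],
        "position": issue.span.start + 1,
        "span": [issue.span.start, issue.span.end],
        "offending": offending,
        "message": issue.message,
    }


def _suggestion_to_dict(suggestion) -> dict:
    return {
        "rank": suggestion.rank,
        "description": suggestion.description,
        "replacement": (
            {
                "span": [suggestion.replacement.start, suggestion.replacement.end],
                "text": suggestion.replacement.text,
            }
            if suggestion.replacement is not None
            else None
        ),
        "alternatives": [
            {"id": c.id, "term": c.term} for c in suggestion.alternatives
        ],
    }


def batch_to_dict(batch: BatchReport) -> dict:
    return {
        "summary": {
            "totalOccurrences": batch.total_occurrences,
            "uniqueExpressions": batch.unique_expressions,
            "invalidExpressions": sum(
                1 for r in batch.per_expression if r.issues
            ),
            "categoryFrequencies": {
                code: batch.per_category_frequency[code]
                for code in sorted(batch.per_category_frequency)
            },
        },
        "expressions": [
            {
                "expression": report.expression,
                "valid": not report.issues,
                "issues": [
                    {
                        "issue": _issue_to_dict(issue),
                        "suggestions": [
                            _suggestion_to_dict(s) for s in suggestions
                        ],
                    }
                    for issue, suggestions in report.issues
                ],
                "residualValid": (
                    report.residual.valid if report.residual is not None else None
                ),
            }
            for report in batch.per_expression
        ],
    }


def write_report(batch: BatchReport, out: str | Path, format: str = "text") -> None:
    """Write the downloadable error report, deterministically byte-for-byte."""
    if format == "json":
        with open(out, "w", encoding="utf-8") as handle:
            json.dump(batch_to_dict(batch), handle, indent=2, ensure_ascii=False)
            handle.write("\n")
        return
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    with open(out, "w", encoding="utf-8") as handle:
        handle.write(format_text_report(batch))


def format_text_report(batch: BatchReport) -> str:
    lines = [
        "Postcoordinated expression validation report",
        "============================================",
        f"Expressions: {batch.total_occurrences} total, "
        f"{batch.unique_expressions} unique",
        f"Invalid unique expressions: "
        f"{sum(1 for r in batch.per_expression if r.issues)}",
    ]
    if batch.per_category_frequency:
        lines.append("Error categories:")
        for code in sorted(batch.per_category_frequency):
            label = CATEGORY_LABELS[IssueCode(code)]
            lines.append(f"  {label}: {batch.per_category_frequency[code]}")
    for report in batch.per_expression:
        if not report.issues:
            continue
        lines.append("")
        lines.append(f"Expression: {report.expression}")
        for issue, suggestions in report.issues:
            label = CATEGORY_LABELS[issue.code]
            lines.append(
                f"  [{label}] position {issue.span.start + 1}: {issue.message}"
            )
            for i, suggestion in enumerate(suggestions, start=1):
                lines.append(f"    {i}. {suggestion.description}")
        if report.residual is not None:
            state = "valid" if report.residual.valid else "still invalid"
            lines.append(
                f"  After applying rank-1 suggestions: {state} "
                f"({report.residual.expression})"
            )
    lines.append("")
    return "\n".join(lines)


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)
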