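"""Syntactic and semantic validation of postcoordinated expressions.

Mirrors the initial-validation step of a terminology server's
``$validate-code`` locally: an expression is parsed, its codes resolved
against the snapshot, its focus concepts assigned to Concept-Model domains,
and every attribute relation checked for attribute validity, range
membership, cardinality, and grouping. Findings are machine-coded into nine
error categories so that a category-specific correction suggestion can be
generated for each.

Stage order (later stages are skipped when an earlier one makes them
meaningless):

1. parse — bracket problems become GROUPING_ERROR, malformed id tokens
   MALFORMED_SCTID, other character problems SYNTAX_CHAR_ERROR; any of these
   halts semantic checking;
2. code resolution — unknown ids are MALFORMED_SCTID (and halt the semantic
   stages: domain and cardinality analysis over unresolvable codes would
   cascade), known-but-inactive ids are INACTIVE_CONCEPT;
3. focus-domain analysis — multiple focus concepts whose domain sets share
   no member are MULTI_FOCUS_DOMAIN_MISMATCH;
4. per-relation checks — INVALID_ATTRIBUTE / INVALID_DOMAIN /
   INVALID_ATTRIBUTE_VALUE per the disambiguation rule in `_check_relation`;
5. cardinality counting per attribute (whole expression and within each
   role group) — CARDINALITY_VIOLATION;
6. grouping requirement — an ungrouped relation whose rule demands grouping
   is a GROUPING_ERROR.

Inactive concepts still participate in domain and range checks (stage 2 does
not halt on them), so one expression can carry both an INACTIVE_CONCEPT and
a semantic issue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

from . import ecl, mrcm, scg
from .terminology import TerminologyGraph, is_valid_sctid


class IssueCode(str, Enum):
    INVALID_ATTRIBUTE = "INVALID_ATTRIBUTE"
    INVALID_ATTRIBUTE_VALUE = "INVALID_ATTRIBUTE_VALUE"
    INVALID_DOMAIN = "INVALID_DOMAIN"
    MULTI_FOCUS_DOMAIN_MISMATCH = "MULTI_FOCUS_DOMAIN_MISMATCH"
    GROUPING_ERROR = "GROUPING_ERROR"
    INACTIVE_CONCEPT = "INACTIVE_CONCEPT"
    MALFORMED_SCTID = "MALFORMED_SCTID"
    CARDINALITY_VIOLATION = "CARDINALITY_VIOLATION"
    SYNTAX_CHAR_ERROR = "SYNTAX_CHAR_ERROR"


#: Human-readable category labels, as rendered in reports.
CATEGORY_LABELS = {
    IssueCode.INVALID_ATTRIBUTE: "Invalid attribute",
    IssueCode.INVALID_ATTRIBUTE_VALUE: "Invalid attribute value",
    IssueCode.INVALID_DOMAIN: "Invalid domain",
    IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH: "Different domains with multiple focus concepts",
    IssueCode.GROUPING_ERROR: "Incorrect grouping",
    IssueCode.INACTIVE_CONCEPT: "Inactivated code",
    IssueCode.MALFORMED_SCTID: "Syntactically incorrect code",
    IssueCode.CARDINALITY_VIOLATION: "Cardinality violation",
    IssueCode.SYNTAX_CHAR_ERROR: "Further syntactic error",
}


@dataclass(frozen=True)
class ValidationIssue:
    code: IssueCode
    span: scg.SourceSpan
    offending: Union[scg.ConceptRef, str]
    message: str
    context: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class ValidationResult:
    expression: str
    valid: bool
    issues: tuple[ValidationIssue, ...]
    ast: Optional[scg.Expression] = field(default=None, compare=False)


class ConfigurationError(Exception):
    """Validation was attempted without a loaded snapshot or model."""


def _pos(span: scg.SourceSpan) -> str:
    return f"position {span.start + 1}"


def _ref_label(ref: scg.ConceptRef) -> str:
    return f"{ref.id} |{ref.term}|" if ref.term else ref.id


def _syntax_issue_to_validation(issue: scg.SyntaxIssue) -> ValidationIssue:
    if issue.code in (scg.SyntaxCode.UNBALANCED_BRACKET, scg.SyntaxCode.MISSING_BRACKET):
        code = IssueCode.GROUPING_ERROR
        message = (
            f"Bracket problem at {_pos(issue.span)}: found {issue.found!r}, "
            f"expected {issue.expected!r}."
        )
    elif issue.code == scg.SyntaxCode.MALFORMED_ID_TOKEN:
        code = IssueCode.MALFORMED_SCTID
        message = (
            f"Identifier {issue.found!r} at {_pos(issue.span)} is not a valid "
            "SCTID (6-18 digits required)."
        )
    else:
        code = IssueCode.SYNTAX_CHAR_ERROR
        message = (
            f"Character {issue.found!r} at {_pos(issue.span)} does not conform "
            f"to the Compositional Grammar (expected {issue.expected})."
        )
    return ValidationIssue(
        code=code,
        span=issue.span,
        offending=issue.found,
        message=message,
        context={"syntax": issue},
    )


def _admitting_domains(
    attribute: str,
    value_focus: list[str],
    model: mrcm.ProcessedConceptModel,
    graph: TerminologyGraph,
) -> set[str]:
    """Domains whose own rule for *attribute* admits the value (every focus
    concept of a nested value must satisfy the range)."""
    out = set()
    for domain_id, domain in model.domains.items():
        for rule in domain.rules:
            if rule.attribute != attribute:
                continue
            node = model.constraint(rule.range_constraint)
            if all(
                ecl.in_value_set(v, node, graph, active_only=False)
                for v in value_focus
            ):
                out.add(domain_id)
                break
    return out


def validate(
    text: str,
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
) -> ValidationResult:
    """Run the full pipeline on one expression; issues are ordered by span."""
    if graph is None or model is None:
        raise ConfigurationError("terminology graph and concept model required")

    parsed = scg.parse_expression(text)
    if isinstance(parsed, list):
        issues = [_syntax_issue_to_validation(iss) for iss in parsed]
        issues.sort(key=lambda i: (i.span.start, i.code.value))
        return ValidationResult(text, False, tuple(issues), ast=None)
    ast = parsed

    issues: list[ValidationIssue] = []

    # stage 2: code resolution
    malformed = False
    for ref in ast.concept_refs():
        if not is_valid_sctid(ref.id) or ref.id not in graph:
            malformed = True
            issues.append(
                ValidationIssue(
                    IssueCode.MALFORMED_SCTID,
                    ref.span,
                    ref,
                    f"Identifier {ref.id} at {_pos(ref.span)} does not resolve "
                    "to any concept in the loaded edition.",
                    context={"digit_sequence": ref.id},
                )
            )
        elif not graph.is_active(ref.id):
            issues.append(
                ValidationIssue(
                    IssueCode.INACTIVE_CONCEPT,
                    ref.span,
                    ref,
                    f"Concept {_ref_label(ref)} at {_pos(ref.span)} is inactive "
                    "in the loaded edition.",
                    context={},
                )
            )
    if malformed:
        issues.sort(key=lambda i: (i.span.start, i.code.value))
        return ValidationResult(text, False, tuple(issues), ast=ast)

    # stage 3: focus-domain analysis
    focus_domains = {
        ref.id: mrcm.domains_of(ref.id, model, graph) for ref in ast.focus
    }
    union_domains: set[str] = set()
    for doms in focus_domains.values():
        union_domains |= doms
    if len(ast.focus) > 1:
        shared = None
        for doms in focus_domains.values():
            shared = set(doms) if shared is None else shared & doms
        if not shared:
            span = scg.SourceSpan(ast.focus[0].span.start, ast.focus[-1].span.end)
            issues.append(
                ValidationIssue(
                    IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH,
                    span,
                    ast.focus[0],
                    "The focus concepts belong to different domains with no "
                    "domain in common: "
                    + "; ".join(
                        f"{fid}: {sorted(doms) or ['(none)']}"
                        for fid, doms in focus_domains.items()
                    )
                    + ".",
                    context={"focus_domains": {k: sorted(v) for k, v in focus_domains.items()}},
                )
            )

    merged_rules = {r.attribute: r for r in mrcm.rules_for(union_domains, model)}

    # stage 4: per-relation attribute / domain / range checks
    for relation, group_index in _relations_with_group(ast):
        issue = _check_relation(
            relation, union_domains, merged_rules, model, graph
        )
        if issue is not None:
            issues.append(issue)

    # stage 5: cardinality
    issues.extend(_check_cardinalities(ast, merged_rules, text))

    # stage 6: grouping requirement
    for relation in ast.ungrouped:
        rule = merged_rules.get(relation.attribute.id)
        if rule is not None and rule.grouped:
            issues.append(
                ValidationIssue(
                    IssueCode.GROUPING_ERROR,
                    relation.span,
                    relation.attribute,
                    f"Attribute {_ref_label(relation.attribute)} at "
                    f"{_pos(relation.span)} must appear inside a role group.",
                    context={"kind": "should_be_grouped", "relation_span": relation.span},
                )
            )

    issues.sort(key=lambda i: (i.span.start, i.code.value))
    return ValidationResult(text, not issues, tuple(issues), ast=ast)


def _relations_with_group(ast: scg.Expression):
    for relation in ast.ungrouped:
        yield relation, None
    for index, group in enumerate(ast.groups):
        for relation in group.relations:
            yield relation, index


def _value_focus_ids(relation: scg.AttributeRelation) -> list[str]:
    if isinstance(relation.value, scg.Expression):
        return [ref.id for ref in relation.value.focus]
    return [relation.value.id]


def _check_relation(
    relation: scg.AttributeRelation,
    union_domains: set[str],
    merged_rules: dict[str, mrcm.AttributeRule],
    model: mrcm.ProcessedConceptModel,
    graph: TerminologyGraph,
) -> Optional[ValidationIssue]:
    """Disambiguation rule for a failing relation.

    ``admitting`` is the set of domains whose own rule admits the
    (attribute, value) pair. If it meets the focus domains the relation is
    fine. Otherwise: valid somewhere else -> INVALID_DOMAIN (the relation is
    semantically correct but does not match the focus concept's domain);
    attribute known in the focus domains but value out of range ->
    INVALID_ATTRIBUTE_VALUE; anything else -> INVALID_ATTRIBUTE. The three
    outcomes are exhaustive and mutually exclusive.
    """
    attribute = relation.attribute
    value_focus = _value_focus_ids(relation)

    if attribute.id not in model.all_attributes:
        return ValidationIssue(
            IssueCode.INVALID_ATTRIBUTE,
            attribute.span,
            attribute,
            f"Concept {_ref_label(attribute)} at {_pos(attribute.span)} is not "
            "a valid attribute.",
            context={"relation_span": relation.span, "value_focus": value_focus},
        )

    admitting = _admitting_domains(attribute.id, value_focus, model, graph)
    if admitting & union_domains:
        return None
    if admitting:
        return ValidationIssue(
            IssueCode.INVALID_DOMAIN,
            relation.span,
            attribute,
            f"The attribute relation at {_pos(relation.span)} is semantically "
            "correct but does not match the domain of the focus concept; it is "
            f"valid in: {', '.join(sorted(admitting))}.",
            context={
                "admitting_domains": sorted(admitting),
                "focus_domains": sorted(union_domains),
            },
        )
    rule = merged_rules.get(attribute.id)
    if rule is not None:
        return ValidationIssue(
            IssueCode.INVALID_ATTRIBUTE_VALUE,
            relation.span,
            attribute,
            f"The value of attribute {_ref_label(attribute)} at "
            f"{_pos(relation.span)} is outside the permitted range "
            f"{rule.range_constraint!r}.",
            context={
                "range_constraint": rule.range_constraint,
                "value_focus": value_focus,
                "relation_span": relation.span,
            },
        )
    return ValidationIssue(
        IssueCode.INVALID_ATTRIBUTE,
        attribute.span,
        attribute,
        f"Attribute {_ref_label(attribute)} at {_pos(attribute.span)} is not "
        "valid in the domain of the focus concept (nor is the relation valid "
        "in any other domain).",
        context={"relation_span": relation.span, "value_focus": value_focus},
    )


def _check_cardinalities(
    ast: scg.Expression,
    merged_rules: dict[str, mrcm.AttributeRule],
    text: str,
) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []

    # whole-expression attribute cardinality
    counts: dict[str, list[scg.AttributeRelation]] = {}
    for relation in ast.all_relations():
        counts.setdefault(relation.attribute.id, []).append(relation)
    for attr_id, relations in sorted(counts.items()):
        rule = merged_rules.get(attr_id)
        if rule is None:
            continue
        count = len(relations)
        if not rule.attribute_cardinality.allows(count):
            issues.append(
                _cardinality_issue(
                    relations[-1], rule.attribute_cardinality, count,
                    scope="expression", group_index=None,
                    relations=relations,
                )
            )
    # minimum occurrences of mandatory attributes
    for attr_id, rule in sorted(merged_rules.items()):
        if rule.attribute_cardinality.min > 0 and attr_id not in counts:
            span = scg.SourceSpan(0, max(len(text), 1))
            issues.append(
                ValidationIssue(
                    IssueCode.CARDINALITY_VIOLATION,
                    span,
                    attr_id,
                    f"Attribute {attr_id} must occur at least "
                    f"{rule.attribute_cardinality.min} time(s) "
                    f"(cardinality {rule.attribute_cardinality}) but is absent.",
                    context={
                        "attribute": attr_id,
                        "cardinality": str(rule.attribute_cardinality),
                        "count": 0,
                        "scope": "expression",
                        "direction": "min",
                    },
                )
            )
    # in-group cardinality (maxima only; in-group minima are not enforced)
    for group_index, group in enumerate(ast.groups):
        group_counts: dict[str, list[scg.AttributeRelation]] = {}
        for relation in group.relations:
            group_counts.setdefault(relation.attribute.id, []).append(relation)
        for attr_id, relations in sorted(group_counts.items()):
            rule = merged_rules.get(attr_id)
            if rule is None:
                continue
            count = len(relations)
            if rule.in_group_cardinality.max is not None and count > rule.in_group_cardinality.max:
                issues.append(
                    _cardinality_issue(
                        relations[-1], rule.in_group_cardinality, count,
                        scope="group", group_index=group_index,
                        relations=relations,
                    )
                )
    return issues


def _cardinality_issue(
    relation: scg.AttributeRelation,
    cardinality: mrcm.Cardinality,
    count: int,
    scope: str,
    group_index: Optional[int],
    relations: list[scg.AttributeRelation],
) -> ValidationIssue:
    where = "within one role group" if scope == "group" else "in the expression"
    direction = "min" if count < cardinality.min else "max"
    return ValidationIssue(
        IssueCode.CARDINALITY_VIOLATION,
        relation.span,
        relation.attribute,
        f"Attribute {_ref_label(relation.attribute)} occurs {count} time(s) "
        f"{where} but its cardinality is {cardinality}.",
        context={
            "attribute": relation.attribute.id,
            "cardinality": str(cardinality),
            "count": count,
            "scope": scope,
            "direction": direction,
            "group_index": group_index,
            "relation_spans": [r.span for r in relations],
            "grouped": scope == "group",
        },
    )


def categorize(result: ValidationResult) -> dict[IssueCode, list[ValidationIssue]]:
    """Partition a result's issues by error category; counts sum to the total."""
    out: dict[IssueCode, list[ValidationIssue]] = {}
    for issue in result.issues:
        out.setdefault(issue.code, []).append(issue)
    return out
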