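"""Per-category correction suggestions and the apply-and-revalidate loop.

For every validation issue a list of concrete, ranked suggestions is
generated. A suggestion may carry a machine-applicable *replacement edit*
(span + replacement text on the original source); the invariant, enforced at
construction, is that applying the edit yields text the parser accepts.
Edits are suggestions, not autonomous repairs: applying the rank-1 edits and
revalidating is offered as one explicit step, and iterating to a fixpoint is
the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Union

from . import ecl, mrcm, scg
from .terminology import TerminologyGraph
from .validator import (
    CATEGORY_LABELS,
    IssueCode,
    ValidationIssue,
    ValidationResult,
    validate,
)


class CorrectionError(Exception):
    """Issue and AST are inconsistent (the issue was not produced on this source)."""


@dataclass(frozen=True)
class Edit:
    """A contiguous text edit; ``start == end`` is a pure insertion."""

    start: int
    end: int
    text: str

    def apply(self, source: str) -> str:
        return source[: self.start] + self.text + source[self.end :]


@dataclass(frozen=True)
class Candidate:
    """A concept offered as an alternative."""

    id: str
    term: Optional[str]

    def label(self) -> str:
        return f"{self.id} |{self.term}|" if self.term else self.id


@dataclass(frozen=True)
class CorrectionSuggestion:
    category: IssueCode
    description: str
    replacement: Optional[Edit]
    alternatives: tuple = ()
    rank: int = 1


@dataclass(frozen=True)
class CorrectionReport:
    expression: str
    issues: tuple[tuple[ValidationIssue, tuple[CorrectionSuggestion, ...]], ...]
    residual: Optional[ValidationResult] = None


def _parses(text: str) -> bool:
    return isinstance(scg.parse_expression(text), scg.Expression)


def _token_overlap(term_a: Optional[str], term_b: Optional[str]) -> bool:
    if not term_a or not term_b:
        return False
    tokens_a = {t.lower() for t in term_a.split()}
    tokens_b = {t.lower() for t in term_b.split()}
    return bool(tokens_a & tokens_b)


def rank_alternatives(
    candidates: list[Candidate], original_term: Optional[str]
) -> list[Candidate]:
    """Stable preference order: candidates whose term tokens overlap the
    original ``|term|`` text first, then ascending id."""
    return sorted(
        candidates,
        key=lambda c: (0 if _token_overlap(c.term, original_term) else 1, c.id),
    )


def _candidate(graph: TerminologyGraph, concept_id: str) -> Candidate:
    term = graph.term(concept_id) if concept_id in graph else None
    return Candidate(concept_id, term)


def _focus_domains(
    ast: scg.Expression, model: mrcm.ProcessedConceptModel, graph: TerminologyGraph
) -> set[str]:
    out: set[str] = set()
    for ref in ast.focus:
        if ref.id in graph:
            out |= mrcm.domains_of(ref.id, model, graph)
    return out


def _first_parseable(
    source: str, edits: list[tuple[Edit, str]], category: IssueCode
) -> list[CorrectionSuggestion]:
    """Turn candidate edits into suggestions, keeping only those whose
    application parses; ranks follow the surviving order."""
    out = []
    for edit, description in edits:
        if _parses(edit.apply(source)):
            out.append(
                CorrectionSuggestion(
                    category=category,
                    description=description,
                    replacement=edit,
                    rank=len(out) + 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# per-category suggestion builders

def _suggest_invalid_attribute(issue, ast, graph, model):
    value_focus = issue.context.get("value_focus", [])
    domains = _focus_domains(ast, model, graph)
    rules = mrcm.rules_for(domains, model)
    candidates: list[tuple[Candidate, str]] = []
    for rule in rules:
        node = model.constraint(rule.range_constraint)
        if value_focus and all(
            ecl.in_value_set(v, node, graph, active_only=False) for v in value_focus
        ):
            candidates.append((_candidate(graph, rule.attribute), rule.range_constraint))
    original_term = issue.offending.term if isinstance(issue.offending, scg.ConceptRef) else None
    ranked = rank_alternatives([c for c, _ in candidates], original_term)
    # revalidate each substitution; alternatives that leave residual errors
    # (e.g. a cardinality conflict with an existing relation) rank last
    residual_issues = {}
    for cand in ranked:
        edit = Edit(issue.span.start, issue.span.end, cand.label())
        result = validate(edit.apply(ast.source), graph, model)
        residual_issues[cand.id] = len(result.issues)
    ranked = sorted(ranked, key=lambda c: residual_issues[c.id])
    ranges = {c.id: rng for c, rng in candidates}
    suggestions = []
    for i, cand in enumerate(ranked, start=1):
        edit = Edit(issue.span.start, issue.span.end, cand.label())
        if not _parses(edit.apply(ast.source)):
            continue
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"Replace the invalid attribute with {cand.label()} "
                    f"(value range: {ranges[cand.id]})."
                ),
                replacement=edit,
                alternatives=(cand,),
                rank=i,
            )
        )
    if not suggestions:
        domain_list = ", ".join(sorted(domains)) or "(none)"
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    "No attribute of the focus concept's domain(s) "
                    f"[{domain_list}] accepts the current value; change the "
                    "attribute value or create the expression with a "
                    "different focus concept."
                ),
                replacement=None,
            )
        )
    return suggestions


def _near_relatives(graph: TerminologyGraph, concept_id: str, max_steps: int = 2):
    """(concept, distance) for IS-A neighbours within ``max_steps`` up or down."""
    seen = {concept_id: 0}
    frontier = [concept_id]
    for step in range(1, max_steps + 1):
        next_frontier = []
        for cid in frontier:
            record = graph.record(cid)
            neighbours = set(record.parents)
            neighbours |= {
                c for c in graph.concepts if cid in graph.concepts[c].parents
            }
            for n in neighbours:
                if n not in seen:
                    seen[n] = step
                    next_frontier.append(n)
        frontier = next_frontier
    seen.pop(concept_id)
    return seen


def _suggest_invalid_value(issue, ast, graph, model, max_alternatives=10):
    range_text = issue.context.get("range_constraint", "")
    relation = _find_relation(ast, issue.context.get("relation_span"))
    if relation is None or isinstance(relation.value, scg.Expression):
        return [
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"The value is outside the permitted range {range_text!r}; "
                    "choose a value from that range."
                ),
                replacement=None,
            )
        ]
    value_ref = relation.value
    node = model.constraint(range_text)
    relatives = _near_relatives(graph, value_ref.id)
    in_range = [
        (dist, cid)
        for cid, dist in relatives.items()
        if graph.is_active(cid) and ecl.in_value_set(cid, node, graph)
    ]
    in_range.sort()
    suggestions = []
    for i, (dist, cid) in enumerate(in_range[:max_alternatives], start=1):
        cand = _candidate(graph, cid)
        edit = Edit(value_ref.span.start, value_ref.span.end, cand.label())
        if not _parses(edit.apply(ast.source)):
            continue
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"Replace the value with {cand.label()} "
                    f"({dist} IS-A step(s) away; permitted range: {range_text})."
                ),
                replacement=edit,
                alternatives=(cand,),
                rank=i,
            )
        )
    if not suggestions:
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"No nearby concept falls inside the permitted range "
                    f"{range_text!r}; choose a value from that range."
                ),
                replacement=None,
            )
        )
    return suggestions


def _suggest_invalid_domain(issue, ast, graph, model):
    admitting = issue.context.get("admitting_domains", [])
    cands = tuple(_candidate(graph, d) for d in admitting)
    listing = ", ".join(c.label() for c in cands)
    return [
        CorrectionSuggestion(
            category=issue.code,
            description=(
                "The attribute relation is semantically correct but the focus "
                f"concept's domain does not allow it; it is valid in: {listing}. "
                "Use a focus concept from one of these domains."
            ),
            replacement=None,
            alternatives=cands,
        )
    ]


def _suggest_multi_focus(issue, ast, graph, model):
    focus_domains = issue.context.get("focus_domains", {})
    listing = "; ".join(
        f"{_candidate(graph, fid).label()} -> {', '.join(doms) if doms else '(no domain)'}"
        for fid, doms in focus_domains.items()
    )
    return [
        CorrectionSuggestion(
            category=issue.code,
            description=(
                f"The focus concepts belong to different domains: {listing}. "
                "Keep only focus concepts that share a domain."
            ),
            replacement=None,
            alternatives=tuple(
                _candidate(graph, fid) for fid in focus_domains
            ),
        )
    ]


def _suggest_grouping(issue, ast, graph, model, source: str):
    if issue.context.get("kind") == "should_be_grouped":
        span = issue.context["relation_span"]
        edit = Edit(span.start, span.end, "{" + source[span.start : span.end] + "}")
        return _first_parseable(
            source,
            [(edit, "Enclose the attribute relation in a role group: { ... }.")],
            issue.code,
        )
    syntax: scg.SyntaxIssue = issue.context.get("syntax")
    edits: list[tuple[Edit, str]] = []
    if syntax is None:
        return [
            CorrectionSuggestion(
                category=issue.code,
                description="Check the role-group brackets of the expression.",
                replacement=None,
            )
        ]
    if syntax.code == scg.SyntaxCode.MISSING_BRACKET:
        open_at = syntax.insert_at if syntax.insert_at is not None else syntax.span.start
        edits.append(
            (
                Edit(open_at, open_at, "{"),
                f"Insert '{{' at position {open_at + 1}; the group closes at "
                f"position {syntax.span.end}.",
            )
        )
        edits.append(
            (
                Edit(syntax.span.end - 1, syntax.span.end, ""),
                f"Delete the stray '}}' at position {syntax.span.end}.",
            )
        )
    elif syntax.found in ("{", "("):
        closer = "}" if syntax.found == "{" else ")"
        close_at = syntax.insert_at if syntax.insert_at is not None else len(source)
        edits.append(
            (
                Edit(close_at, close_at, closer),
                f"Insert '{closer}' at position {close_at + 1} to close the "
                f"bracket opened at position {syntax.span.start + 1}.",
            )
        )
        edits.append(
            (
                Edit(syntax.span.start, syntax.span.end, ""),
                f"Delete the unmatched '{syntax.found}' at position "
                f"{syntax.span.start + 1}.",
            )
        )
    else:
        edits.append(
            (
                Edit(syntax.span.start, syntax.span.end, ""),
                f"Delete the unmatched '{syntax.found}' at position "
                f"{syntax.span.start + 1}.",
            )
        )
        opener = "{" if syntax.found == "}" else "("
        edits.append(
            (
                Edit(0, 0, opener),
                f"Insert '{opener}' where the group should start.",
            )
        )
    suggestions = _first_parseable(source, edits, issue.code)
    if not suggestions:
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description="Rebalance the brackets of the expression.",
                replacement=None,
            )
        )
    return suggestions


def _suggest_inactive(issue, ast, graph, model, source: str):
    ref = issue.offending
    entries = graph.resolve_historical(ref.id)
    refset_names = {
        "900000000000527005": "SAME AS",
        "900000000000526001": "REPLACED BY",
    }
    suggestions = []
    for i, (refset_id, target) in enumerate(entries, start=1):
        cand = _candidate(graph, target)
        name = refset_names.get(refset_id, refset_id)
        if graph.is_active(target):
            edit = Edit(ref.span.start, ref.span.end, cand.label())
            if not _parses(edit.apply(source)):
                continue
            suggestions.append(
                CorrectionSuggestion(
                    category=issue.code,
                    description=(
                        f"Replace the inactivated concept with its {name} "
                        f"association target {cand.label()}."
                    ),
                    replacement=edit,
                    alternatives=(cand,),
                    rank=len(suggestions) + 1,
                )
            )
        else:
            suggestions.append(
                CorrectionSuggestion(
                    category=issue.code,
                    description=(
                        f"The {name} association target {cand.label()} is itself "
                        "inactive; resolve the replacement chain manually."
                    ),
                    replacement=None,
                    alternatives=(cand,),
                    rank=len(suggestions) + 1,
                )
            )
    if not suggestions:
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    "No historical association is recorded for this inactivated "
                    "concept; choose an active replacement manually."
                ),
                replacement=None,
            )
        )
    return suggestions


def _suggest_malformed(issue, ast, graph, model, source: str, max_candidates=50):
    sequence = issue.context.get("digit_sequence")
    if sequence is None:
        syntax = issue.context.get("syntax")
        sequence = syntax.found if syntax is not None else None
    if not sequence or not sequence.isdigit():
        return [
            CorrectionSuggestion(
                category=issue.code,
                description="The identifier cannot be matched to any concept.",
                replacement=None,
            )
        ]
    candidates = sorted(graph.find_ids_containing(sequence))[:max_candidates]
    original_term = (
        issue.offending.term if isinstance(issue.offending, scg.ConceptRef) else None
    )
    surviving = []
    for cid in candidates:
        cand = _candidate(graph, cid)
        edit = Edit(issue.span.start, issue.span.end, cand.label())
        result = validate(edit.apply(source), graph, model)
        if result.valid:
            surviving.append((cand, edit))
    ranked = rank_alternatives([c for c, _ in surviving], original_term)
    edits = {c.id: e for c, e in surviving}
    suggestions = [
        CorrectionSuggestion(
            category=issue.code,
            description=(
                f"Replace the unresolvable identifier {sequence} with "
                f"{cand.label()} (contains the digit sequence and revalidates "
                "cleanly)."
            ),
            replacement=edits[cand.id],
            alternatives=(cand,),
            rank=i,
        )
        for i, cand in enumerate(ranked, start=1)
    ]
    if not suggestions:
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"No concept containing the digit sequence {sequence} fits "
                    "the expression; correct the identifier manually."
                ),
                replacement=None,
            )
        )
    return suggestions


def _find_relation(ast: Optional[scg.Expression], span) -> Optional[scg.AttributeRelation]:
    if ast is None or span is None:
        return None
    for relation in ast.all_relations():
        if relation.span == span:
            return relation
    return None


def _rebuild_without(ast: scg.Expression, span) -> scg.Expression:
    """Copy of the expression with the relation at *span* removed."""
    ungrouped = tuple(r for r in ast.ungrouped if r.span != span)
    groups = []
    for group in ast.groups:
        relations = tuple(r for r in group.relations if r.span != span)
        if relations:
            groups.append(scg.RoleGroup(relations, group.span))
    return dc_replace(ast, ungrouped=ungrouped, groups=tuple(groups))


def _suggest_cardinality(issue, ast, graph, model, source: str):
    ctx = issue.context
    cardinality = ctx.get("cardinality", "?")
    attribute = ctx.get("attribute", "?")
    if ctx.get("direction") == "min":
        return [
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"Attribute {_candidate(graph, attribute).label()} violates "
                    f"its minimum cardinality ({cardinality}); add the missing "
                    "attribute relation."
                ),
                replacement=None,
            )
        ]
    spans = ctx.get("relation_spans", [])
    extra_span = spans[-1] if spans else None
    if ctx.get("grouped"):
        # move the surplus grouped relation to an additional role group
        relation = _find_relation(ast, extra_span)
        if relation is not None:
            stripped = _rebuild_without(ast, extra_span)
            moved = dc_replace(
                stripped,
                groups=stripped.groups + (scg.RoleGroup((relation,), relation.span),),
            )
            new_text = scg.serialize_canonical(moved)
            if _parses(new_text):
                return [
                    CorrectionSuggestion(
                        category=issue.code,
                        description=(
                            f"Attribute {_candidate(graph, attribute).label()} "
                            f"exceeds its in-group cardinality ({cardinality}); "
                            "move the surplus relation to an additional role group."
                        ),
                        replacement=Edit(0, len(source), new_text),
                    )
                ]
    if extra_span is not None:
        relation = _find_relation(ast, extra_span)
        if relation is not None:
            stripped = _rebuild_without(ast, extra_span)
            new_text = scg.serialize_canonical(stripped)
            if _parses(new_text):
                return [
                    CorrectionSuggestion(
                        category=issue.code,
                        description=(
                            f"Attribute {_candidate(graph, attribute).label()} "
                            f"exceeds its cardinality ({cardinality}); delete the "
                            "surplus ungrouped relation."
                        ),
                        replacement=Edit(0, len(source), new_text),
                    )
                ]
    return [
        CorrectionSuggestion(
            category=issue.code,
            description=(
                f"Attribute {attribute} violates cardinality {cardinality}; "
                "remove or regroup the surplus relations."
            ),
            replacement=None,
        )
    ]


def _suggest_syntax_char(issue, ast, graph, model, source: str):
    syntax: scg.SyntaxIssue = issue.context.get("syntax")
    span = issue.span
    found = syntax.found if syntax is not None else str(issue.offending)
    edits: list[tuple[Edit, str]] = [
        (
            Edit(span.start, span.end, ""),
            f"Delete the character {found!r} at position {span.start + 1}.",
        )
    ]
    for repl in (":", "=", ",", "+"):
        edits.append(
            (
                Edit(span.start, span.end, repl),
                f"Replace the character {found!r} at position {span.start + 1} "
                f"with {repl!r}.",
            )
        )
    suggestions = _first_parseable(source, edits, issue.code)
    if not suggestions:
        suggestions.append(
            CorrectionSuggestion(
                category=issue.code,
                description=(
                    f"The character {found!r} at position {span.start + 1} does "
                    "not conform to the Compositional Grammar; remove or replace it."
                ),
                replacement=None,
            )
        )
    return suggestions


def suggest(
    issue: ValidationIssue,
    ast: Optional[scg.Expression],
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
    source: Optional[str] = None,
) -> list[CorrectionSuggestion]:
    """Category-specific suggestions for one issue.

    ``ast`` may be None for issues raised before parsing succeeded (bracket
    and character errors); ``source`` must then carry the expression text.
    """
    if ast is not None:
        source = ast.source
    if source is None:
        raise CorrectionError("either ast or source must be provided")
    if ast is not None and issue.span.end > len(ast.source):
        raise CorrectionError("issue span lies outside the expression source")

    if issue.code == IssueCode.INVALID_ATTRIBUTE:
        return _suggest_invalid_attribute(issue, ast, graph, model)
    if issue.code == IssueCode.INVALID_ATTRIBUTE_VALUE:
        return _suggest_invalid_value(issue, ast, graph, model)
    if issue.code == IssueCode.INVALID_DOMAIN:
        return _suggest_invalid_domain(issue, ast, graph, model)
    if issue.code == IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH:
        return _suggest_multi_focus(issue, ast, graph, model)
    if issue.code == IssueCode.GROUPING_ERROR:
        return _suggest_grouping(issue, ast, graph, model, source)
    if issue.code == IssueCode.INACTIVE_CONCEPT:
        return _suggest_inactive(issue, ast, graph, model, source)
    if issue.code == IssueCode.MALFORMED_SCTID:
        return _suggest_malformed(issue, ast, graph, model, source)
    if issue.code == IssueCode.CARDINALITY_VIOLATION:
        return _suggest_cardinality(issue, ast, graph, model, source)
    return _suggest_syntax_char(issue, ast, graph, model, source)


def build_report(
    text: str,
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
) -> CorrectionReport:
    """Validate an expression and attach suggestions to every issue.

    When an inactivity issue and a semantic issue touch the same stretch of
    source, only the inactivity suggestion keeps its replacement edit (the
    semantic picture is re-derived on revalidation after the replacement).
    """
    result = validate(text, graph, model)
    inactive_spans = [
        issue.span for issue in result.issues if issue.code == IssueCode.INACTIVE_CONCEPT
    ]

    def overlaps_inactive(edit: Edit) -> bool:
        return any(
            edit.start < span.end and span.start < edit.end for span in inactive_spans
        )

    pairs = []
    for issue in result.issues:
        suggestions = suggest(issue, result.ast, graph, model, source=text)
        if issue.code != IssueCode.INACTIVE_CONCEPT:
            suggestions = [
                dc_replace(s, replacement=None)
                if s.replacement is not None and overlaps_inactive(s.replacement)
                else s
                for s in suggestions
            ]
        pairs.append((issue, tuple(suggestions)))
    return CorrectionReport(expression=text, issues=tuple(pairs), residual=None)


def apply_and_revalidate(
    report: CorrectionReport,
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
) -> CorrectionReport:
    """Apply every issue's rank-1 replacement edit and revalidate once.

    Edits are applied in descending span order so earlier offsets stay valid;
    edits overlapping an already-applied edit are skipped. The original
    ``expression`` field is left untouched; the corrected text is the
    residual result's expression.
    """
    edits: list[Edit] = []
    for _issue, suggestions in report.issues:
        ranked = sorted(suggestions, key=lambda s: s.rank)
        if ranked and ranked[0].replacement is not None:
            edits.append(ranked[0].replacement)
    text = report.expression
    applied: list[tuple[int, int]] = []
    for edit in sorted(edits, key=lambda e: e.start, reverse=True):
        if any(edit.start < end and start < edit.end for start, end in applied):
            continue
        # a pure insertion at the boundary of an applied edit is also a conflict
        if edit.start == edit.end and any(
            start <= edit.start <= end for start, end in applied
        ):
            continue
        text = edit.apply(text)
        applied.append((edit.start, edit.end))
    residual = validate(text, graph, model)
    return CorrectionReport(
        expression=report.expression, issues=report.issues, residual=residual
    )
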