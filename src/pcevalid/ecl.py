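"""Evaluator for the Expression Constraint Language subset used for validation.

Supported: self, ``<<`` descendant-or-self, ``<`` descendant, ``OR``, ``AND``,
parenthesized grouping, and ``^`` memberOf over a reference set with an
optional ``[targetComponentId]``/``[referencedComponentId]`` selector and an
optional ``{{ M referencedComponentId = ... }}`` member filter. Constraint
evaluation runs against the local :class:`~pcevalid.terminology.TerminologyGraph`
instead of a terminology server's ``$expand``.

Out of scope (full ECL): refinements, cardinality, nested member filters,
wildcards, reverse attributes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .terminology import TerminologyGraph


class EclError(Exception):
    pass


class EclParseError(EclError):
    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (offset {offset})")


class EclEvaluationError(EclError):
    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"constraint references unknown concept {concept_id}")


@dataclass(frozen=True)
class EclNode:
    kind: str  # SELF, DESC_OR_SELF, DESC, OR, AND, MEMBER_OF
    concept: Optional[str] = None  # leaf kinds
    children: tuple["EclNode", ...] = ()  # OR / AND, >= 2
    refset: Optional[str] = None  # MEMBER_OF
    selector: str = "referencedComponentId"  # MEMBER_OF
    filter_concept: Optional[str] = None  # MEMBER_OF member filter


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<dbrace_open>\{\{)|(?P<dbrace_close>\}\})|(?P<desc_self><<)"
    r"|(?P<desc><)|(?P<member>\^)|(?P<lparen>\()|(?P<rparen>\))"
    r"|(?P<lbracket>\[)|(?P<rbracket>\])|(?P<eq>=)"
    r"|(?P<id>\d+)|(?P<term>\|[^|]*\|)|(?P<word>[A-Za-z][A-Za-z]*))"
)


def _tokens(text: str) -> list[tuple[str, str, int]]:
    out = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            offset = len(text) - len(stripped)
            raise EclParseError(f"unsupported token {stripped[0]!r}", offset)
        kind = match.lastgroup
        out.append((kind, match.group(kind), match.start(kind)))
        pos = match.end()
    out.append(("eof", "", len(text)))
    return out


class _EclParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokens(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos]

    def advance(self):
        tok = self.tokens[self.pos]
        if tok[0] != "eof":
            self.pos += 1
        return tok

    def expect(self, kind: str, what: str):
        tok = self.peek()
        if tok[0] != kind:
            raise EclParseError(f"expected {what}, found {tok[1]!r}", tok[2])
        return self.advance()

    def concept_id(self) -> str:
        tok = self.expect("id", "concept identifier")
        if self.peek()[0] == "term":
            self.advance()
        return tok[1]

    def atom(self) -> EclNode:
        kind, text, offset = self.peek()
        if kind == "desc_self":
            self.advance()
            return EclNode("DESC_OR_SELF", concept=self.concept_id())
        if kind == "desc":
            self.advance()
            return EclNode("DESC", concept=self.concept_id())
        if kind == "member":
            self.advance()
            return self.member_of()
        if kind == "lparen":
            self.advance()
            node = self.disjunction()
            self.expect("rparen", ")")
            return node
        if kind == "id":
            return EclNode("SELF", concept=self.concept_id())
        raise EclParseError(f"unsupported token {text!r}", offset)

    def member_of(self) -> EclNode:
        selector = "referencedComponentId"
        if self.peek()[0] == "lbracket":
            self.advance()
            word = self.expect("word", "component selector")
            if word[1] not in ("referencedComponentId", "targetComponentId"):
                raise EclParseError(f"unknown selector {word[1]!r}", word[2])
            selector = word[1]
            self.expect("rbracket", "]")
        refset = self.concept_id()
        filter_concept = None
        if self.peek()[0] == "dbrace_open":
            self.advance()
            marker = self.expect("word", "filter marker M")
            if marker[1] != "M":
                raise EclParseError(f"unsupported member filter {marker[1]!r}", marker[2])
            keyword = self.expect("word", "referencedComponentId")
            if keyword[1] != "referencedComponentId":
                raise EclParseError(
                    f"unsupported filter field {keyword[1]!r}", keyword[2]
                )
            self.expect("eq", "=")
            filter_concept = self.concept_id()
            self.expect("dbrace_close", "}}")
        return EclNode(
            "MEMBER_OF", refset=refset, selector=selector, filter_concept=filter_concept
        )

    def disjunction(self) -> EclNode:
        first = self.atom()
        op = None
        children = [first]
        while self.peek()[0] == "word" and self.peek()[1] in ("OR", "AND"):
            tok = self.advance()
            if op is None:
                op = tok[1]
            elif tok[1] != op:
                raise EclParseError(
                    "mixed OR/AND require parentheses", tok[2]
                )
            children.append(self.atom())
        if op is None:
            return first
        return EclNode(op, children=tuple(children))


def parse_ecl(text: str) -> EclNode:
    """Parse an ECL fragment of the supported subset; unknown syntax is
    rejected with the offending token and offset."""
    if not text.strip():
        raise EclParseError("empty constraint", 0)
    parser = _EclParser(text)
    node = parser.disjunction()
    tok = parser.peek()
    if tok[0] != "eof":
        raise EclParseError(f"unexpected trailing token {tok[1]!r}", tok[2])
    return node


def evaluate_ecl(node: EclNode, graph: TerminologyGraph) -> set[str]:
    """Expand a constraint to the set of matching concept ids.

    Expansion mirrors value-set semantics: inactive concepts never appear in
    SELF/DESC results. MEMBER_OF returns the selected component of every
    matching refset entry regardless of activity — resolving inactivated
    codes is its purpose.
    """
    if node.kind in ("SELF", "DESC_OR_SELF", "DESC"):
        if node.concept not in graph:
            raise EclEvaluationError(node.concept)
        if node.kind == "SELF":
            return {node.concept} if graph.is_active(node.concept) else set()
        result = graph.descendants(node.concept, active_only=True)
        if node.kind == "DESC_OR_SELF" and graph.is_active(node.concept):
            result = result | {node.concept}
        return result
    if node.kind == "OR":
        out: set[str] = set()
        for child in node.children:
            out |= evaluate_ecl(child, graph)
        return out
    if node.kind == "AND":
        sets = [evaluate_ecl(child, graph) for child in node.children]
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out
    if node.kind == "MEMBER_OF":
        out = set()
        for entry in graph.associations:
            if entry.refset_id != node.refset:
                continue
            if (
                node.filter_concept is not None
                and entry.referenced_component != node.filter_concept
            ):
                continue
            selected = (
                entry.target_component
                if node.selector == "targetComponentId"
                else entry.referenced_component
            )
            out.add(selected)
        return out
    raise EclError(f"unknown node kind {node.kind}")


def in_value_set(
    concept: str,
    node: EclNode,
    graph: TerminologyGraph,
    active_only: bool = True,
) -> bool:
    """Membership test equivalent to ``concept in evaluate_ecl(node, graph)``
    (when ``active_only``), short-circuiting via subsumption instead of
    materializing the expansion.

    With ``active_only=False`` the activity filter is waived: the validator
    uses this so an inactivated concept still resolves its domain and range
    (inactivity is reported by its own error category).
    """
    if concept not in graph:
        raise EclEvaluationError(concept)
    if node.kind in ("SELF", "DESC_OR_SELF", "DESC"):
        if node.concept not in graph:
            raise EclEvaluationError(node.concept)
        if active_only and not graph.is_active(concept):
            return False
        if node.kind == "SELF":
            return concept == node.concept
        if node.kind == "DESC":
            return concept != node.concept and graph.is_descendant_or_self(
                concept, node.concept
            )
        return graph.is_descendant_or_self(concept, node.concept)
    if node.kind == "OR":
        return any(in_value_set(concept, c, graph, active_only) for c in node.children)
    if node.kind == "AND":
        return all(in_value_set(concept, c, graph, active_only) for c in node.children)
    return concept in evaluate_ecl(node, graph)
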