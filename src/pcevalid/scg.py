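"""Parser and canonical serializer for SNOMED Compositional Grammar expressions.

Supports definition-status markers (``===`` / ``<<<``), multiple focus
concepts joined by ``+``, ``:`` refinement with ungrouped attribute relations,
``{}`` role groups, and fully recursive nested expressions in parentheses as
attribute values. Concrete-value literals (``#``-prefixed strings/numbers)
are out of scope.

Every AST node carries a :class:`SourceSpan` of 0-based character offsets on
the raw input so that diagnoses and correction edits can point at exact
positions (reports render them 1-based for humans). Whitespace is
insignificant outside ``|...|`` term delimiters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union


@dataclass(frozen=True)
class SourceSpan:
    start: int  # 0-based, inclusive
    end: int  # exclusive

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


class SyntaxCode(str, Enum):
    UNBALANCED_BRACKET = "UNBALANCED_BRACKET"
    MISSING_BRACKET = "MISSING_BRACKET"
    ILLEGAL_CHARACTER = "ILLEGAL_CHARACTER"
    MALFORMED_ID_TOKEN = "MALFORMED_ID_TOKEN"
    EMPTY_CONSTRUCT = "EMPTY_CONSTRUCT"


@dataclass(frozen=True)
class SyntaxIssue:
    """A position-annotated syntax diagnosis.

    ``insert_at`` carries a secondary offset where relevant: for an unmatched
    opening bracket, the offset where its closer should be inserted; for
    MISSING_BRACKET the span start is itself the insertion offset and the
    span end marks where the group closes.
    """

    code: SyntaxCode
    span: SourceSpan
    found: str = ""
    expected: str = ""
    insert_at: Optional[int] = None


@dataclass(frozen=True)
class ConceptRef:
    id: str
    term: Optional[str]  # text between |...|, stripped; None when absent
    span: SourceSpan


@dataclass(frozen=True)
class AttributeRelation:
    attribute: ConceptRef
    value: Union[ConceptRef, "Expression"]
    span: SourceSpan

    @property
    def value_is_expression(self) -> bool:
        return isinstance(self.value, Expression)


@dataclass(frozen=True)
class RoleGroup:
    relations: tuple[AttributeRelation, ...]  # non-empty
    span: SourceSpan


@dataclass(frozen=True)
class Expression:
    """A parsed postcoordinated expression (the AST)."""

    definition_status: str  # "equivalent" (===, default) or "subtype-of" (<<<)
    focus: tuple[ConceptRef, ...]  # non-empty, joined by "+"
    ungrouped: tuple[AttributeRelation, ...]
    groups: tuple[RoleGroup, ...]
    source: str

    def all_relations(self) -> list[AttributeRelation]:
        out = list(self.ungrouped)
        for group in self.groups:
            out.extend(group.relations)
        return out

    def concept_refs(self) -> list[ConceptRef]:
        """Every concept reference in the expression, nested values included."""
        refs = list(self.focus)
        for rel in self.all_relations():
            refs.append(rel.attribute)
            if isinstance(rel.value, Expression):
                refs.extend(rel.value.concept_refs())
            else:
                refs.append(rel.value)
        return refs


# ---------------------------------------------------------------------------
# tokenizer

_SYMBOLS = {":": "COLON", "{": "LBRACE", "}": "RBRACE", "(": "LPAREN",
            ")": "RPAREN", "=": "EQUALS", "+": "PLUS", ",": "COMMA"}


@dataclass(frozen=True)
class _Token:
    kind: str  # ID, TERM, one of _SYMBOLS values, EQV, SUBTYPE, EOF
    text: str
    span: SourceSpan


def _tokenize(text: str) -> tuple[list[_Token], list[SyntaxIssue]]:
    tokens: list[_Token] = []
    issues: list[SyntaxIssue] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            span = SourceSpan(i, j)
            token = _Token("ID", text[i:j], span)
            if not (6 <= j - i <= 18):
                issues.append(
                    SyntaxIssue(
                        SyntaxCode.MALFORMED_ID_TOKEN,
                        span,
                        found=text[i:j],
                        expected="SCTID of 6-18 digits",
                    )
                )
            tokens.append(token)
            i = j
            continue
        if ch == "|":
            j = text.find("|", i + 1)
            if j == -1:
                issues.append(
                    SyntaxIssue(
                        SyntaxCode.ILLEGAL_CHARACTER,
                        SourceSpan(i, i + 1),
                        found="|",
                        expected="closing |",
                    )
                )
                i = n
                continue
            tokens.append(_Token("TERM", text[i + 1 : j].strip(), SourceSpan(i, j + 1)))
            i = j + 1
            continue
        if text.startswith("===", i):
            tokens.append(_Token("EQV", "===", SourceSpan(i, i + 3)))
            i += 3
            continue
        if text.startswith("<<<", i):
            tokens.append(_Token("SUBTYPE", "<<<", SourceSpan(i, i + 3)))
            i += 3
            continue
        if ch in _SYMBOLS:
            tokens.append(_Token(_SYMBOLS[ch], ch, SourceSpan(i, i + 1)))
            i += 1
            continue
        issues.append(
            SyntaxIssue(
                SyntaxCode.ILLEGAL_CHARACTER,
                SourceSpan(i, i + 1),
                found=ch,
                expected="Compositional Grammar character",
            )
        )
        i += 1
    tokens.append(_Token("EOF", "", SourceSpan(max(n - 1, 0), max(n, 1))))
    return tokens, issues


# ---------------------------------------------------------------------------
# bracket diagnosis

def _masked(text: str) -> str:
    """Replace |term| contents with spaces so brackets inside terms are ignored."""
    out = list(text)
    i, n = 0, len(text)
    while i < n:
        if text[i] == "|":
            j = text.find("|", i + 1)
            if j == -1:
                j = n - 1
            for k in range(i, min(j + 1, n)):
                out[k] = " "
            i = j + 1
        else:
            i += 1
    return "".join(out)


def diagnose_brackets(text: str) -> list[SyntaxIssue]:
    """Stack-based matcher for ``{}`` and ``()`` imbalances.

    An unmatched opener yields UNBALANCED_BRACKET at the opener's offset with
    ``insert_at`` where the closer belongs (end of input). A bare ``}``
    following attribute relations yields MISSING_BRACKET whose span runs from
    the offset where ``{`` should be inserted to just past the stray ``}``.
    """
    masked = _masked(text)
    issues: list[SyntaxIssue] = []
    stack: list[tuple[str, int]] = []
    # offset just past the most recent top-level boundary (':' or ',' at depth 0)
    boundary = 0
    for i, ch in enumerate(masked):
        if ch in "{(":
            stack.append((ch, i))
        elif ch in "})":
            opener = "{" if ch == "}" else "("
            if stack and stack[-1][0] == opener:
                stack.pop()
            elif ch == "}" and not any(b == "{" for b, _ in stack):
                # bare '}' after relations: infer the missing '{'
                start = boundary
                while start < i and masked[start].isspace():
                    start += 1
                if start < i:
                    issues.append(
                        SyntaxIssue(
                            SyntaxCode.MISSING_BRACKET,
                            SourceSpan(start, i + 1),
                            found="}",
                            expected="{",
                            insert_at=start,
                        )
                    )
                else:
                    issues.append(
                        SyntaxIssue(
                            SyntaxCode.UNBALANCED_BRACKET,
                            SourceSpan(i, i + 1),
                            found=ch,
                            expected=opener,
                        )
                    )
            else:
                issues.append(
                    SyntaxIssue(
                        SyntaxCode.UNBALANCED_BRACKET,
                        SourceSpan(i, i + 1),
                        found=ch,
                        expected=opener,
                    )
                )
        elif ch == ":" and not stack:
            boundary = i + 1
        elif ch == "," and not stack:
            boundary = i + 1
    for opener, offset in stack:
        closer = "}" if opener == "{" else ")"
        issues.append(
            SyntaxIssue(
                SyntaxCode.UNBALANCED_BRACKET,
                SourceSpan(offset, offset + 1),
                found=opener,
                expected=closer,
                insert_at=len(text),
            )
        )
    issues.sort(key=lambda iss: iss.span.start)
    return issues


# ---------------------------------------------------------------------------
# recursive-descent parser

class _ParseFailure(Exception):
    def __init__(self, issue: SyntaxIssue):
        self.issue = issue
        super().__init__(issue.code.value)


class _Parser:
    def __init__(self, tokens: list[_Token], source: str):
        self.tokens = tokens
        self.source = source
        self.pos = 0

    def peek(self) -> _Token:
        return self.tokens[self.pos]

    def advance(self) -> _Token:
        tok = self.tokens[self.pos]
        if tok.kind != "EOF":
            self.pos += 1
        return tok

    def fail(self, expected: str) -> _ParseFailure:
        tok = self.peek()
        if tok.kind == "EOF":
            return _ParseFailure(
                SyntaxIssue(
                    SyntaxCode.EMPTY_CONSTRUCT, tok.span, found="end of input",
                    expected=expected,
                )
            )
        return _ParseFailure(
            SyntaxIssue(
                SyntaxCode.ILLEGAL_CHARACTER, tok.span, found=tok.text,
                expected=expected,
            )
        )

    def concept_ref(self) -> ConceptRef:
        tok = self.peek()
        if tok.kind != "ID":
            raise self.fail("concept identifier")
        self.advance()
        term = None
        end = tok.span.end
        if self.peek().kind == "TERM":
            term_tok = self.advance()
            term = term_tok.text or None
            end = term_tok.span.end
        return ConceptRef(tok.text, term, SourceSpan(tok.span.start, end))

    def value(self) -> Union[ConceptRef, Expression]:
        if self.peek().kind == "LPAREN":
            open_tok = self.advance()
            inner = self.expression(start=open_tok.span.end)
            if self.peek().kind != "RPAREN":
                raise self.fail(")")
            close = self.advance()
            return Expression(
                inner.definition_status,
                inner.focus,
                inner.ungrouped,
                inner.groups,
                source=self.source,
            )
        return self.concept_ref()

    def relation(self) -> AttributeRelation:
        attribute = self.concept_ref()
        if self.peek().kind != "EQUALS":
            raise self.fail("=")
        self.advance()
        value = self.value()
        end = value.span.end if isinstance(value, ConceptRef) else self._last_end()
        return AttributeRelation(attribute, value, SourceSpan(attribute.span.start, end))

    def _last_end(self) -> int:
        return self.tokens[self.pos - 1].span.end

    def group(self) -> RoleGroup:
        open_tok = self.advance()  # LBRACE
        if self.peek().kind == "RBRACE":
            close = self.advance()
            raise _ParseFailure(
                SyntaxIssue(
                    SyntaxCode.EMPTY_CONSTRUCT,
                    SourceSpan(open_tok.span.start, close.span.end),
                    found="{}",
                    expected="attribute relation",
                )
            )
        relations = [self.relation()]
        while self.peek().kind == "COMMA":
            self.advance()
            relations.append(self.relation())
        if self.peek().kind != "RBRACE":
            raise self.fail("}")
        close = self.advance()
        return RoleGroup(
            tuple(relations), SourceSpan(open_tok.span.start, close.span.end)
        )

    def expression(self, start: int = 0) -> Expression:
        status = "equivalent"
        if self.peek().kind in ("EQV", "SUBTYPE"):
            status = "subtype-of" if self.peek().kind == "SUBTYPE" else "equivalent"
            self.advance()
        focus = [self.concept_ref()]
        while self.peek().kind == "PLUS":
            self.advance()
            focus.append(self.concept_ref())
        ungrouped: list[AttributeRelation] = []
        groups: list[RoleGroup] = []
        if self.peek().kind == "COLON":
            self.advance()
            if self.peek().kind in ("EOF", "RPAREN"):
                raise _ParseFailure(
                    SyntaxIssue(
                        SyntaxCode.EMPTY_CONSTRUCT,
                        self.peek().span,
                        found="end of refinement",
                        expected="attribute relation or role group",
                    )
                )
            while True:
                if self.peek().kind == "LBRACE":
                    groups.append(self.group())
                else:
                    ungrouped.append(self.relation())
                if self.peek().kind == "COMMA":
                    self.advance()
                    continue
                break
        return Expression(
            status, tuple(focus), tuple(ungrouped), tuple(groups), source=self.source
        )


def parse_expression(text: str) -> Union[Expression, list[SyntaxIssue]]:
    """Parse Compositional Grammar text.

    Returns either a fully spanned :class:`Expression` or a non-empty list of
    :class:`SyntaxIssue` records — never both. Tokenizer and bracket
    diagnoses are gathered before grammar errors so that a mangled expression
    reports every character/bracket problem at once.
    """
    if not text.strip():
        return [
            SyntaxIssue(
                SyntaxCode.EMPTY_CONSTRUCT,
                SourceSpan(0, max(len(text), 1)),
                found="empty input",
                expected="expression",
            )
        ]
    tokens, issues = _tokenize(text)
    issues = issues + diagnose_brackets(text)
    if issues:
        issues.sort(key=lambda iss: (iss.span.start, iss.code.value))
        return issues
    parser = _Parser(tokens, text)
    try:
        ast = parser.expression()
    except _ParseFailure as failure:
        return [failure.issue]
    if parser.peek().kind != "EOF":
        tok = parser.peek()
        return [
            SyntaxIssue(
                SyntaxCode.ILLEGAL_CHARACTER,
                tok.span,
                found=tok.text,
                expected="end of expression",
            )
        ]
    return ast


# ---------------------------------------------------------------------------
# canonical serialization

def _ref_str(ref: ConceptRef) -> str:
    return f"{ref.id} |{ref.term}|" if ref.term else ref.id


def _value_key(value: Union[ConceptRef, Expression]) -> str:
    if isinstance(value, Expression):
        return "(" + serialize_canonical(value) + ")"
    return value.id


def _relation_str(rel: AttributeRelation) -> str:
    if isinstance(rel.value, Expression):
        value = "(" + serialize_canonical(rel.value) + ")"
    else:
        value = _ref_str(rel.value)
    return f"{_ref_str(rel.attribute)} = {value}"


def serialize_canonical(ast: Expression) -> str:
    """Deterministic canonical text for an expression.

    Single spaces; terms preserved when present; focus concepts, ungrouped
    relations, and relations within each group sorted by ascending id; groups
    sorted by their (sorted) first relation. Whitespace/order variants of the
    same expression therefore serialize identically, which is what batch
    deduplication keys on.
    """
    focus = sorted(ast.focus, key=lambda r: r.id)
    ungrouped = sorted(ast.ungrouped, key=lambda r: (r.attribute.id, _value_key(r.value)))
    groups = []
    for group in ast.groups:
        rels = sorted(group.relations, key=lambda r: (r.attribute.id, _value_key(r.value)))
        groups.append(rels)
    groups.sort(key=lambda rels: [(r.attribute.id, _value_key(r.value)) for r in rels])

    prefix = "<<< " if ast.definition_status == "subtype-of" else ""
    out = prefix + " + ".join(_ref_str(r) for r in focus)
    parts = [", ".join(_relation_str(r) for r in rels) for rels in [ungrouped] if rels]
    parts += ["{ " + ", ".join(_relation_str(r) for r in rels) + " }" for rels in groups]
    if parts:
        out += " : " + ", ".join(parts)
    return out


def structure(ast: Expression) -> tuple:
    """Span-free canonical structure, for round-trip / equality comparisons."""

    def ref(r: ConceptRef):
        return (r.id, r.term)

    def rel(r: AttributeRelation):
        value = structure(r.value) if isinstance(r.value, Expression) else ref(r.value)
        return (ref(r.attribute), value)

    ungrouped = tuple(sorted((rel(r) for r in ast.ungrouped), key=repr))
    groups = tuple(
        sorted(
            (tuple(sorted((rel(r) for r in g.relations), key=repr)) for g in ast.groups),
            key=repr,
        )
    )
    focus = tuple(sorted((ref(r) for r in ast.focus), key=repr))
    return (ast.definition_status, focus, ungrouped, groups)
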