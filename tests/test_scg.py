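"""Compositional Grammar parsing, bracket diagnosis, canonical serialization."""

import pytest
from hypothesis import given, strategies as st

from pcevalid import scg
from pcevalid.fixtures import INTRO_EXPRESSION
from pcevalid.scg import (
    Expression,
    SyntaxCode,
    diagnose_brackets,
    parse_expression,
    serialize_canonical,
    structure,
)


def test_intro_expression_shape():
    ast = parse_expression(INTRO_EXPRESSION)
    assert isinstance(ast, Expression)
    assert [f.id for f in ast.focus] == ["1155942004"]
    assert ast.focus[0].term == "Allergy to metal and/or metal compound"
    assert ast.ungrouped == ()
    assert len(ast.groups) == 1
    assert [r.attribute.id for r in ast.groups[0].relations] == [
        "719722006",
        "246075003",
    ]


def test_bare_concept():
    ast = parse_expression("138875005")
    assert isinstance(ast, Expression)
    assert ast.focus[0].id == "138875005"
    assert ast.focus[0].term is None
    assert not ast.ungrouped and not ast.groups
    assert ast.definition_status == "equivalent"


def test_definition_status_markers():
    assert parse_expression("<<< 138875005").definition_status == "subtype-of"
    assert parse_expression("=== 138875005").definition_status == "equivalent"


def test_multiple_focus_and_ungrouped_and_nested():
    ast = parse_expression(
        "100001001 + 100002005 : 100003002 = (100004008 : 100005009 = 100006003)"
    )
    assert [f.id for f in ast.focus] == ["100001001", "100002005"]
    assert len(ast.ungrouped) == 1
    nested = ast.ungrouped[0].value
    assert isinstance(nested, Expression)
    assert nested.focus[0].id == "100004008"


def test_illegal_character_after_colon():
    # ":@" instead of ":" before the refinement
    text = INTRO_EXPRESSION.replace(":", ":@", 1)
    issues = parse_expression(text)
    assert isinstance(issues, list)
    at = [i for i in issues if i.code == SyntaxCode.ILLEGAL_CHARACTER]
    assert at and at[0].found == "@"
    assert text[at[0].span.start] == "@"


def test_empty_input_reports_empty_construct():
    issues = parse_expression("   ")
    assert issues[0].code == SyntaxCode.EMPTY_CONSTRUCT
    assert issues[0].span.start == 0


def test_short_id_token_flagged():
    issues = parse_expression("12345")
    assert isinstance(issues, list)
    assert issues[0].code == SyntaxCode.MALFORMED_ID_TOKEN


def test_duplicate_relations_preserved():
    ast = parse_expression("100001001 : {100003002 = 100004008, 100003002 = 100004008}")
    assert len(ast.groups[0].relations) == 2


def test_parse_never_returns_ast_and_issues():
    for text in [INTRO_EXPRESSION, "138875005", "abc", "100001001 : {", ""]:
        out = parse_expression(text)
        assert isinstance(out, Expression) or (
            isinstance(out, list) and len(out) > 0
        )


def test_balanced_expression_has_no_bracket_issues():
    assert diagnose_brackets(INTRO_EXPRESSION) == []


def test_deleted_closing_brace_diagnosed_at_opener():
    text = INTRO_EXPRESSION[: INTRO_EXPRESSION.rindex("}")]
    issues = diagnose_brackets(text)
    assert len(issues) == 1
    issue = issues[0]
    assert issue.code == SyntaxCode.UNBALANCED_BRACKET
    assert text[issue.span.start] == "{"
    assert issue.expected == "}"
    assert issue.insert_at == len(text)


def test_missing_opener_inferred_from_bare_closer():
    text = "100001001 : 100003002 = 100004008}"
    issues = diagnose_brackets(text)
    assert len(issues) == 1
    issue = issues[0]
    assert issue.code == SyntaxCode.MISSING_BRACKET
    # insertion offset at the first relation's start
    assert issue.span.start == text.index("100003002")
    assert issue.span.end == len(text)


def test_brackets_inside_terms_ignored():
    assert diagnose_brackets("100001001 |term with { brace|") == []


def test_issue_spans_index_real_positions():
    for text in ["@", "100001001 : {", "100001001}", "1 : = }"]:
        out = parse_expression(text)
        assert isinstance(out, list)
        for issue in out:
            assert 0 <= issue.span.start < issue.span.end <= max(len(text), 1)


def test_canonical_whitespace_insensitivity():
    variant = INTRO_EXPRESSION.replace(": ", ":   ").replace(", ", " ,  ")
    a = serialize_canonical(parse_expression(INTRO_EXPRESSION))
    b = serialize_canonical(parse_expression(variant))
    assert a == b


def test_canonical_group_order_invariance():
    one = "100001001 : {100003002 = 100004008}, {100002005 = 100005009}"
    two = "100001001 : {100002005 = 100005009}, {100003002 = 100004008}"
    assert serialize_canonical(parse_expression(one)) == serialize_canonical(
        parse_expression(two)
    )


def test_canonical_without_terms_has_no_pipes():
    text = "100001001 : {100003002 = 100004008}"
    assert "|" not in serialize_canonical(parse_expression(text))


# ---------------------------------------------------------------------------
# round-trip property: parse -> serialize -> parse is a fixed point

_ids = st.sampled_from(
    ["100001001", "100002005", "100003002", "100004008", "100005009", "1155942004"]
)
_terms = st.one_of(st.none(), st.sampled_from(["Alpha beta", "Gamma (delta)"]))


@st.composite
def _expressions(draw, depth=0):
    def ref():
        cid = draw(_ids)
        term = draw(_terms)
        return f"{cid} |{term}|" if term else cid

    def relation():
        if depth < 1 and draw(st.booleans()):
            nested = draw(_expressions(depth=depth + 1))
            return f"{ref()} = ({nested})"
        return f"{ref()} = {ref()}"

    focus = " + ".join(ref() for _ in range(draw(st.integers(1, 2))))
    n_ungrouped = draw(st.integers(0, 2))
    n_groups = draw(st.integers(0, 2))
    parts = [relation() for _ in range(n_ungrouped)]
    for _ in range(n_groups):
        inner = ", ".join(relation() for _ in range(draw(st.integers(1, 2))))
        parts.append("{" + inner + "}")
    text = focus
    if parts:
        text += " : " + ", ".join(parts)
    return text


@given(_expressions())
def test_round_trip_fixed_point(text):
    ast = parse_expression(text)
    assert isinstance(ast, Expression), text
    canonical = serialize_canonical(ast)
    ast2 = parse_expression(canonical)
    assert isinstance(ast2, Expression), canonical
    assert structure(ast) == structure(ast2)
    assert serialize_canonical(ast2) == canonical
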