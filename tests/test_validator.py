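"""Nine-category validation pipeline on crafted expressions and corpora."""

import pytest

from pcevalid.fixtures import (
    INTRO_EXPRESSION,
    INVALID_ATTRIBUTE_EXPRESSION,
    CorpusSpec,
    generate_corpus,
)
from pcevalid.validator import IssueCode, categorize, validate


def codes(result):
    return [issue.code for issue in result.issues]


def test_intro_expression_is_valid(graph, model):
    result = validate(INTRO_EXPRESSION, graph, model)
    assert result.valid
    assert result.issues == ()


def test_allergic_process_as_attribute_is_invalid_attribute(graph, model):
    result = validate(INVALID_ATTRIBUTE_EXPRESSION, graph, model)
    assert not result.valid
    assert codes(result) == [IssueCode.INVALID_ATTRIBUTE]
    issue = result.issues[0]
    assert issue.offending.id == "472964009"
    # the span points at the second (attribute) use, not the value use
    assert INVALID_ATTRIBUTE_EXPRESSION[issue.span.start :].startswith("472964009")


def test_value_outside_range_is_invalid_attribute_value(graph, model):
    # Causative agent with a body-structure value: valid attribute, bad value
    result = validate(
        "1155942004 : {246075003 |Causative agent| = 990300102}", graph, model
    )
    assert codes(result) == [IssueCode.INVALID_ATTRIBUTE_VALUE]
    assert result.issues[0].context["range_constraint"] == "<< 105590001 |Substance|"


def test_relation_valid_elsewhere_is_invalid_domain(graph, model):
    # substance focus with a clinical-finding relation
    result = validate("256526003 : {246075003 = 990500103}", graph, model)
    assert codes(result) == [IssueCode.INVALID_DOMAIN]
    assert result.issues[0].context["admitting_domains"] == ["404684003"]


def test_disjoint_focus_domains_flagged(graph, model):
    result = validate(
        "990400103 + 990300102 : {246075003 = 990500103}", graph, model
    )
    assert codes(result) == [IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH]


def test_overlapping_focus_domains_accepted(graph, model):
    # two clinical findings share the domain
    result = validate("990400103 + 990400107 : {246075003 = 990500103}", graph, model)
    assert result.valid


def test_inactive_concept_reported_but_semantics_still_checked(graph, model):
    result = validate("1155942004 : {246075003 = 990500109}", graph, model)
    assert codes(result) == [IssueCode.INACTIVE_CONCEPT]
    # inactive value plus out-of-range attribute use elsewhere -> both reported
    result = validate(
        "1155942004 : {246075003 = 990500109, 719722006 = 990300102}", graph, model
    )
    assert set(codes(result)) == {
        IssueCode.INACTIVE_CONCEPT,
        IssueCode.INVALID_ATTRIBUTE_VALUE,
    }


def test_unknown_id_is_malformed_and_halts_semantic_stages(graph, model):
    result = validate("115594200 : {246075003 = 990300102}", graph, model)
    assert codes(result) == [IssueCode.MALFORMED_SCTID]


def test_cardinality_max_within_group(graph, model):
    result = validate(
        "1155942004 : {246075003 = 990500103, 246075003 = 990500104}", graph, model
    )
    assert codes(result) == [IssueCode.CARDINALITY_VIOLATION]
    assert result.issues[0].context["direction"] == "max"
    assert result.issues[0].context["scope"] == "group"


def test_cardinality_min_missing_mandatory_attribute(graph, model):
    result = validate("990200101", graph, model)  # procedure without Method
    assert codes(result) == [IssueCode.CARDINALITY_VIOLATION]
    assert result.issues[0].context["direction"] == "min"
    assert result.issues[0].context["attribute"] == "260686004"


def test_cardinality_max_ungrouped(graph, model):
    result = validate(
        "990200101 : 260686004 = 990100104, 260686004 = 990100105", graph, model
    )
    assert codes(result) == [IssueCode.CARDINALITY_VIOLATION]
    assert result.issues[0].context["scope"] == "expression"


def test_ungrouped_relation_requiring_group(graph, model):
    result = validate("1155942004 : 246075003 = 990500103", graph, model)
    assert codes(result) == [IssueCode.GROUPING_ERROR]
    assert result.issues[0].context["kind"] == "should_be_grouped"


def test_bracket_problem_maps_to_grouping_error(graph, model):
    text = INTRO_EXPRESSION[:-1]  # drop the final '}'
    result = validate(text, graph, model)
    assert codes(result) == [IssueCode.GROUPING_ERROR]


def test_illegal_character_maps_to_syntax_char_error(graph, model):
    text = INTRO_EXPRESSION.replace(":", ":@", 1)
    result = validate(text, graph, model)
    assert codes(result) == [IssueCode.SYNTAX_CHAR_ERROR]


def test_issues_ordered_by_span_and_deterministic(graph, model):
    text = "1155942004 : {246075003 = 990500109, 719722006 = 990300102}"
    first = validate(text, graph, model)
    second = validate(text, graph, model)
    assert first.issues == second.issues
    starts = [issue.span.start for issue in first.issues]
    assert starts == sorted(starts)


def test_categorize_partitions_issues(graph, model):
    valid = validate(INTRO_EXPRESSION, graph, model)
    assert categorize(valid) == {}
    invalid = validate(
        "1155942004 : {246075003 = 990500109, 719722006 = 990500110}", graph, model
    )
    partition = categorize(invalid)
    assert len(partition[IssueCode.INACTIVE_CONCEPT]) == 2
    assert sum(len(v) for v in partition.values()) == len(invalid.issues)


def test_nested_expression_value_checked_against_range(graph, model):
    # Associated with accepts clinical findings, also as nested expressions
    ok = validate(
        "1155942004 : {47429007 = (990400103 : {246075003 = 990500103})}",
        graph,
        model,
    )
    assert ok.valid
    bad = validate("1155942004 : {47429007 = (990100102)}", graph, model)
    assert codes(bad) == [IssueCode.INVALID_ATTRIBUTE_VALUE]


def test_single_error_corpus_label_agreement(graph, model):
    spec = CorpusSpec(
        n_valid=20,
        per_category_counts={code: 5 for code in IssueCode},
        seed=11,
    )
    corpus = generate_corpus(spec, graph, model)
    assert len(corpus) == 20 + 45
    for item in corpus:
        result = validate(item.text, graph, model)
        observed = {issue.code for issue in result.issues}
        expected = set() if item.injected is None else {item.injected}
        assert observed == expected, (item.text, item.provenance)
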