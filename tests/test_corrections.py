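"""Correction suggestions per category and the apply-and-revalidate loop."""

import pytest

from pcevalid import scg
from pcevalid.corrections import (
    Candidate,
    apply_and_revalidate,
    build_report,
    rank_alternatives,
)
from pcevalid.fixtures import (
    INTRO_EXPRESSION,
    INVALID_ATTRIBUTE_EXPRESSION,
    CorpusSpec,
    generate_corpus,
)
from pcevalid.validator import IssueCode, validate


def _suggestions_for(report, code):
    for issue, suggestions in report.issues:
        if issue.code == code:
            return issue, list(suggestions)
    raise AssertionError(f"no issue with code {code}")


def test_invalid_attribute_alternatives_match_worked_example(graph, model):
    report = build_report(INVALID_ATTRIBUTE_EXPRESSION, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.INVALID_ATTRIBUTE)
    alternative_ids = [s.alternatives[0].id for s in suggestions if s.alternatives]
    assert alternative_ids == ["246075003", "47429007"]
    # each alternative carries its value range in the instruction text
    assert "105590001" in suggestions[0].description


def test_applying_causative_agent_repairs_the_expression(graph, model):
    report = build_report(INVALID_ATTRIBUTE_EXPRESSION, graph, model)
    report = apply_and_revalidate(report, graph, model)
    assert report.residual is not None and report.residual.valid
    assert report.expression == INVALID_ATTRIBUTE_EXPRESSION  # source untouched
    corrected = scg.parse_expression(report.residual.expression)
    intro = scg.parse_expression(INTRO_EXPRESSION)
    assert scg.structure(corrected) == scg.structure(intro)


def test_inactive_concept_replacement_edit(graph, model):
    report = build_report("224799004 |Unfamiliar environment|", graph, model)
    issue, suggestions = _suggestions_for(report, IssueCode.INACTIVE_CONCEPT)
    top = suggestions[0]
    assert top.replacement is not None
    assert top.alternatives[0].id == "1186687002"
    assert "REPLACED BY" in top.description
    repaired = top.replacement.apply("224799004 |Unfamiliar environment|")
    assert validate(repaired, graph, model).valid


def test_inactive_suggested_targets_always_active(graph, model):
    for inactive in ("224799004", "990500109", "990500110", "990400106"):
        report = build_report(inactive, graph, model)
        _issue, suggestions = _suggestions_for(report, IssueCode.INACTIVE_CONCEPT)
        for suggestion in suggestions:
            if suggestion.replacement is not None:
                assert all(graph.is_active(c.id) for c in suggestion.alternatives)


def test_malformed_sctid_candidates_revalidate(graph, model):
    # 1155942004 with the final digit dropped
    text = "115594200 : {719722006 = 472964009}"
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.MALFORMED_SCTID)
    candidate_ids = [s.alternatives[0].id for s in suggestions if s.alternatives]
    assert "1155942004" in candidate_ids
    for suggestion in suggestions:
        if suggestion.replacement is not None:
            assert validate(
                suggestion.replacement.apply(text), graph, model
            ).valid


def test_invalid_value_alternatives_are_near_and_in_range(graph, model):
    text = "1155942004 : {246075003 = 990300102}"  # body structure as substance
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.INVALID_ATTRIBUTE_VALUE)
    # no nearby in-range concept exists around a body structure: advisory only
    assert suggestions[0].replacement is None
    # a value one step outside the range does get neighbours
    text = "990300102 : {272741003 = 990100106}"  # qualifier, sibling of Side
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.INVALID_ATTRIBUTE_VALUE)
    with_edits = [s for s in suggestions if s.replacement is not None]
    assert with_edits
    repaired = with_edits[0].replacement.apply(text)
    assert validate(repaired, graph, model).valid


def test_invalid_domain_lists_admitting_domains(graph, model):
    report = build_report("256526003 : {246075003 = 990500103}", graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.INVALID_DOMAIN)
    assert [c.id for c in suggestions[0].alternatives] == ["404684003"]
    assert suggestions[0].replacement is None


def test_multi_focus_suggestion_shows_per_focus_domains(graph, model):
    report = build_report(
        "990400103 + 990300102 : {246075003 = 990500103}", graph, model
    )
    _issue, suggestions = _suggestions_for(
        report, IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH
    )
    ids = {c.id for c in suggestions[0].alternatives}
    assert ids == {"990400103", "990300102"}
    assert "404684003" in suggestions[0].description


def test_grouping_suggestion_closes_group_at_end(graph, model):
    text = INTRO_EXPRESSION[:-1]
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.GROUPING_ERROR)
    top = suggestions[0]
    assert top.replacement is not None
    assert top.replacement.text == "}"
    assert top.replacement.start == len(text)
    assert validate(top.replacement.apply(text), graph, model).valid


def test_should_be_grouped_suggestion_wraps_relation(graph, model):
    text = "1155942004 : 246075003 = 990500103"
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.GROUPING_ERROR)
    repaired = suggestions[0].replacement.apply(text)
    assert validate(repaired, graph, model).valid


def test_syntax_char_suggestion_names_position_and_repairs(graph, model):
    text = INTRO_EXPRESSION.replace(":", ":@", 1)
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.SYNTAX_CHAR_ERROR)
    top = suggestions[0]
    at = text.index("@")
    assert str(at + 1) in top.description
    assert validate(top.replacement.apply(text), graph, model).valid


def test_cardinality_max_grouped_moves_to_new_group(graph, model):
    text = "1155942004 : {246075003 = 990500103, 246075003 = 990500104}"
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.CARDINALITY_VIOLATION)
    repaired = suggestions[0].replacement.apply(text)
    result = validate(repaired, graph, model)
    assert result.valid
    assert len(result.ast.groups) == 2


def test_cardinality_max_ungrouped_deletes_surplus(graph, model):
    text = "990200101 : 260686004 = 990100104, 260686004 = 990100105"
    report = build_report(text, graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.CARDINALITY_VIOLATION)
    repaired = suggestions[0].replacement.apply(text)
    assert validate(repaired, graph, model).valid


def test_cardinality_min_is_advisory(graph, model):
    report = build_report("990200101", graph, model)
    _issue, suggestions = _suggestions_for(report, IssueCode.CARDINALITY_VIOLATION)
    assert suggestions[0].replacement is None
    assert "minimum" in suggestions[0].description


def test_rank_alternatives_id_fallback_and_overlap():
    no_overlap = [
        Candidate("47429007", "Associated with"),
        Candidate("246075003", "Causative agent"),
    ]
    ranked = rank_alternatives(no_overlap, "Allergic process")
    assert [c.id for c in ranked] == ["246075003", "47429007"]
    with_overlap = no_overlap + [Candidate("900000001", "Allergic trigger")]
    ranked = rank_alternatives(with_overlap, "Allergic process")
    assert ranked[0].id == "900000001"
    assert rank_alternatives([no_overlap[0]], None) == [no_overlap[0]]


def test_inactivity_fix_takes_priority_over_semantic_edit(graph, model):
    # inactive value that is also out of range: only the inactivity
    # suggestion keeps a replacement edit on that stretch of source
    text = "1155942004 : {719722006 = 990500109}"
    report = build_report(text, graph, model)
    codes = {issue.code for issue, _ in report.issues}
    assert IssueCode.INACTIVE_CONCEPT in codes
    for issue, suggestions in report.issues:
        if issue.code != IssueCode.INACTIVE_CONCEPT:
            assert all(s.replacement is None for s in suggestions)


def test_repair_is_monotone_on_single_error_mutants(graph, model):
    spec = CorpusSpec(
        n_valid=0,
        per_category_counts={
            IssueCode.INVALID_ATTRIBUTE: 15,
            IssueCode.INACTIVE_CONCEPT: 15,
            IssueCode.MALFORMED_SCTID: 10,
            IssueCode.GROUPING_ERROR: 15,
            IssueCode.SYNTAX_CHAR_ERROR: 15,
            IssueCode.CARDINALITY_VIOLATION: 15,
        },
        seed=5,
    )
    corpus = generate_corpus(spec, graph, model)
    applied = 0
    for item in corpus:
        report = build_report(item.text, graph, model)
        if not any(
            s.replacement is not None
            for _issue, suggestions in report.issues
            for s in suggestions[:1]
        ):
            continue
        report = apply_and_revalidate(report, graph, model)
        applied += 1
        before = sum(1 for _ in report.issues)
        after = len(report.residual.issues)
        assert after < before, (item.text, report.residual.expression)
    assert applied >= 50


def test_valid_expression_report_has_no_issues(graph, model):
    report = build_report(INTRO_EXPRESSION, graph, model)
    assert report.issues == ()
    report = apply_and_revalidate(report, graph, model)
    assert report.residual.valid
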