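"""FHIR/CSV extraction, deduplication, and report round trips."""

import json

import pytest

from pcevalid import fhir_io
from pcevalid.fhir_io import (
    PceOccurrence,
    UnsupportedResourceError,
    batch_to_dict,
    dedupe,
    extract_pces,
    read_expressions_csv,
    read_report,
    validate_batch,
    write_report,
)
from pcevalid.fixtures import INTRO_EXPRESSION, INVALID_ATTRIBUTE_EXPRESSION

SCT = "http://snomed.info/sct"


def _questionnaire(expressions):
    return {
        "resourceType": "Questionnaire",
        "status": "active",
        "item": [
            {
                "linkId": "q1",
                "type": "choice",
                "answerOption": [
                    {"valueCoding": {"system": SCT, "code": expr}}
                    for expr in expressions
                ],
                "item": [
                    {
                        "linkId": "q1.1",
                        "type": "choice",
                        "code": [{"system": SCT, "code": expressions[0]}],
                    }
                ],
            }
        ],
    }


def test_questionnaire_extraction_with_pointers():
    doc = _questionnaire([INTRO_EXPRESSION])
    occurrences = extract_pces(doc)
    assert len(occurrences) == 2
    origins = {o.origin for o in occurrences}
    assert "/item/0/answerOption/0/valueCoding/code" in origins
    assert "/item/0/item/0/code/0/code" in origins
    assert all(o.resource_type == "Questionnaire" for o in occurrences)


def test_precoordinated_codes_skipped():
    doc = _questionnaire(["1155942004"])
    assert extract_pces(doc) == []
    doc = {
        "resourceType": "Questionnaire",
        "item": [
            {
                "answerOption": [
                    {"valueCoding": {"system": "http://loinc.org", "code": "a:b"}}
                ]
            }
        ],
    }
    assert extract_pces(doc) == []


def test_valueset_and_conceptmap_extraction():
    valueset = {
        "resourceType": "ValueSet",
        "compose": {
            "include": [
                {"system": SCT, "concept": [{"code": INTRO_EXPRESSION}]}
            ]
        },
        "expansion": {
            "contains": [
                {
                    "system": SCT,
                    "code": INTRO_EXPRESSION,
                    "contains": [{"system": SCT, "code": INVALID_ATTRIBUTE_EXPRESSION}],
                }
            ]
        },
    }
    occurrences = extract_pces(valueset)
    assert len(occurrences) == 3
    conceptmap = {
        "resourceType": "ConceptMap",
        "group": [
            {
                "source": "http://example.org/oncotree",
                "target": SCT,
                "element": [
                    {
                        "code": "LUNG",
                        "target": [{"code": INTRO_EXPRESSION}],
                    }
                ],
            }
        ],
    }
    occurrences = extract_pces(conceptmap)
    assert len(occurrences) == 1
    assert occurrences[0].origin == "/group/0/element/0/target/0/code"


def test_unknown_resource_type_rejected():
    with pytest.raises(UnsupportedResourceError, match="Patient"):
        extract_pces({"resourceType": "Patient"})


def test_generated_questionnaire_origins_match_bookkeeping(graph, model):
    from pcevalid.fixtures import CorpusSpec, generate_corpus

    corpus = generate_corpus(CorpusSpec(n_valid=5, seed=2), graph, model)
    doc = _questionnaire([item.text for item in corpus])
    occurrences = extract_pces(doc)
    extracted = [
        o.expression
        for o in occurrences
        if o.origin.startswith("/item/0/answerOption")
    ]
    assert extracted == [item.text for item in corpus]


def test_dedupe_whitespace_variants():
    variants = [
        INTRO_EXPRESSION,
        INTRO_EXPRESSION.replace(": ", " :  "),
        INTRO_EXPRESSION.replace(", ", " , "),
    ]
    occurrences = [
        PceOccurrence(v, f"row {i}", "CSV") for i, v in enumerate(variants)
    ]
    grouped = dedupe(occurrences)
    assert len(grouped) == 1
    assert len(next(iter(grouped.values()))) == 3
    assert dedupe([]) == {}


def test_dedupe_keys_unparseable_by_raw_text():
    occurrences = [PceOccurrence("not {an expression", "row 1", "CSV")]
    grouped = dedupe(occurrences)
    assert list(grouped) == ["not {an expression"]


def test_csv_reading(tmp_path):
    path = tmp_path / "expr.csv"
    path.write_text(
        'expression\n"1155942004: {719722006 = 472964009, 246075003 = 256526003}"\n'
        "138875005 + 404684003\n",
        encoding="utf-8",
    )
    occurrences = read_expressions_csv(path)
    assert len(occurrences) == 2
    assert occurrences[0].expression.startswith("1155942004")
    assert occurrences[0].resource_type == "CSV"


def test_batch_frequencies_recount(graph, model):
    occurrences = [
        PceOccurrence(INTRO_EXPRESSION, "row 1", "CSV"),
        PceOccurrence(INTRO_EXPRESSION, "row 2", "CSV"),
        PceOccurrence(INVALID_ATTRIBUTE_EXPRESSION, "row 3", "CSV"),
    ]
    batch = validate_batch(occurrences, graph, model)
    assert batch.total_occurrences == 3
    assert batch.unique_expressions == 2
    recount = {}
    for report in batch.per_expression:
        for issue, _ in report.issues:
            recount[issue.code.value] = recount.get(issue.code.value, 0) + 1
    assert recount == batch.per_category_frequency
    assert batch.per_category_frequency == {"INVALID_ATTRIBUTE": 1}


def test_text_report_structure(graph, model):
    occurrences = [PceOccurrence(INVALID_ATTRIBUTE_EXPRESSION, "row 1", "CSV")]
    batch = validate_batch(occurrences, graph, model)
    text = fhir_io.format_text_report(batch)
    assert "Invalid attribute" in text
    assert "1. " in text and "2. " in text  # numbered alternatives
    clean = validate_batch([PceOccurrence(INTRO_EXPRESSION, "r", "CSV")], graph, model)
    clean_text = fhir_io.format_text_report(clean)
    assert "Invalid" not in clean_text.split("\n\n")[0] or "Invalid unique expressions: 0" in clean_text


def test_report_write_is_deterministic(graph, model, tmp_path):
    occurrences = [PceOccurrence(INVALID_ATTRIBUTE_EXPRESSION, "row 1", "CSV")]
    batch = validate_batch(occurrences, graph, model)
    write_report(batch, tmp_path / "a.txt", format="text")
    write_report(batch, tmp_path / "b.txt", format="text")
    assert (tmp_path / "a.txt").read_bytes() == (tmp_path / "b.txt").read_bytes()


def test_json_report_round_trip(graph, model, tmp_path):
    occurrences = [
        PceOccurrence(INTRO_EXPRESSION, "row 1", "CSV"),
        PceOccurrence(INVALID_ATTRIBUTE_EXPRESSION, "row 2", "CSV"),
    ]
    batch = validate_batch(occurrences, graph, model, apply_suggestions=True)
    out = tmp_path / "report.json"
    write_report(batch, out, format="json")
    assert read_report(out) == batch_to_dict(batch)
    doc = read_report(out)
    assert doc["summary"]["totalOccurrences"] == 2
    assert doc["summary"]["uniqueExpressions"] == 2
    assert doc["summary"]["invalidExpressions"] == 1
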