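# pcevalid

Syntactic and semantic validation of **postcoordinated SNOMED CT expressions
(PCEs)**, with concrete, per-error correction suggestions — entirely against a
local terminology snapshot, with no terminology-server dependency.

## The problem

SNOMED CT cannot precoordinate every clinical circumstance (an allergy to a
cobalt-chromium alloy, say), so its Compositional Grammar lets users *compose*
expressions from released concepts:

```
1155942004 |Allergy to metal and/or metal compound| :
    { 719722006 |Has realization| = 472964009 |Allergic process|,
      246075003 |Causative agent| = 256526003 |Cobalt-chromium alloy| }
```

A valid expression must satisfy the Compositional Grammar (focus concepts,
`:` refinement, `{}` role groups, `attribute = value` relations) **and** the
Concept Model, which assigns every attribute a *domain* (which focus concepts
it may refine), a *range* (which values it accepts, written as an Expression
Constraint Language fragment such as `<< 105590001 |Substance|`), a
cardinality, and a grouping requirement. Getting both layers right by hand is
hard; a failed validation from a terminology server is usually a terse
machine-oriented diagnostic.

`pcevalid` validates expressions locally and classifies every failure into
one of nine error categories — invalid attribute, invalid attribute value,
invalid domain, different domains with multiple focus concepts, incorrect
grouping, inactivated code, syntactically incorrect code, cardinality
violation, further syntactic error — and for each finding generates ranked,
position-annotated correction suggestions, most of them machine-applicable
edits that are guaranteed to re-parse.

## What is inside

| module | role |
| --- | --- |
| `pcevalid.terminology` | RF2-dialect snapshot: concepts, IS-A closure, historical-association refsets (SAME AS / REPLACED BY) |
| `pcevalid.scg` | position-annotated Compositional Grammar parser, bracket diagnosis, canonical serializer |
| `pcevalid.ecl` | Expression Constraint Language subset evaluator (`<<`, `<`, `OR`, `AND`, `^ memberOf` with member filters) |
| `pcevalid.mrcm` | MRCM domain-refset templates decomposed into a processed concept model (JSON round-trip) |
| `pcevalid.validator` | the nine-category validation pipeline |
| `pcevalid.corrections` | per-category suggestion generation and apply-and-revalidate |
| `pcevalid.fhir_io` | PCE extraction from FHIR Questionnaire / ValueSet / ConceptMap JSON and CSV; dedup; error reports |
| `pcevalid.fixtures` | miniature synthetic snapshot + seeded corpora with labeled injected errors |
| `pcevalid.cli` | `pcevalid` console script (validate / validate-file / export-mrcm / gen-fixtures / gen-corpus) |

## Worked example

```sh
pcevalid gen-fixtures --out fx
pcevalid validate --snapshot fx --mrcm fx/mrcm.tsv \
  "1155942004: {719722006 = 472964009, 472964009 = 256526003}"
```

prints (exit status 1, since the expression is invalid):

```
Postcoordinated expression validation report
============================================
Expressions: 1 total, 1 unique
Invalid unique expressions: 1
Error categories:
  Invalid attribute: 1

Expression: 1155942004: {719722006 = 472964009, 472964009 = 256526003}
  [Invalid attribute] position 37: Concept 472964009 at position 37 is not a valid attribute.
    1. Replace the invalid attribute with 246075003 |Causative agent| (value range: << 105590001 |Substance|).
    2. Replace the invalid attribute with 47429007 |Associated with| (value range: << 404684003 |Clinical finding| OR << 105590001 |Substance| OR << 71388002 |Procedure|).
  After applying rank-1 suggestions: valid (1155942004: {719722006 = 472964009, 246075003 |Causative agent| = 256526003})
```

`472964009 |Allergic process|` is a perfectly good concept but not an
attribute; the two suggested replacements are exactly the attributes of the
focus concept's domain whose value range admits the current value
`256526003 |Cobalt-chromium alloy|`, and applying the first one yields an
expression that revalidates cleanly. The same pipeline resolves inactivated
codes through the historical-association refsets: validating `224799004
|Unfamiliar environment (environment)|` proposes its REPLACED BY successor
`1186687002 |Unfamiliar environment (finding)|` as a direct replacement edit.

The library surface mirrors the CLI:

```python
from pcevalid import fixtures, validate, build_report, apply_and_revalidate

fixtures.build_fixture_snapshot("fx")
graph, model = fixtures.load_fixture("fx")
report = build_report("1155942004: {472964009 = 256526003}", graph, model)
report = apply_and_revalidate(report, graph, model)
assert report.residual.valid
```

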