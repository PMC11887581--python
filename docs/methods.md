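# Methods

This note documents the validation model, the design choices made where the
design was genuinely open, the synthetic data the tests run on, and the known
limitations.

## Validation model

A postcoordinated expression is checked in six stages, each stage consuming
the outcome of the previous one:

1. **Parse.** A hand-written, position-annotated recursive-descent parser for
   the Compositional Grammar subset actually used in postcoordination:
   definition-status markers (`===`/`<<<`), multiple `+`-joined focus
   concepts, `:` refinement, ungrouped attribute relations, `{}` role groups,
   and fully recursive parenthesized nested expressions as attribute values.
   Concrete-value literals (`#`-prefixed) are out of scope. Every AST node
   carries a 0-based character span on the raw input; reports render
   positions 1-based. Tokenizer diagnoses (illegal characters, unterminated
   terms, digit runs outside the 6–18 SCTID shape) and a stack-based bracket
   matcher run before grammar errors so a mangled expression reports all its
   character/bracket problems at once. Bracket problems map to the grouping
   category, malformed id tokens to the syntactically-incorrect-code
   category, and all other character problems to the further-syntactic-error
   category; any of them halts semantic checking.
2. **Code resolution.** Each referenced identifier is looked up in the
   snapshot. Unknown (or mis-shaped) identifiers are *syntactically
   incorrect codes*; known-but-inactive concepts are *inactivated codes*.
   An identifier is "unknown" purely by graph lookup — no Verhoeff check
   digit is computed, because an identifier with missing characters is
   detected by failed resolution anyway. An unresolvable identifier halts
   the semantic stages: domain and cardinality analysis over unresolvable
   codes would cascade (a truncated mandatory-attribute id would additionally
   fire a minimum-cardinality violation), defeating one-category-per-error
   reporting. Inactive concepts do *not* halt anything: they keep their
   place in the hierarchy as loaded, so one expression can carry both an
   inactivity finding and an independent semantic finding.
3. **Focus-domain analysis.** Each focus concept is assigned the set of
   Concept-Model domains whose ECL constraint admits it. With multiple focus
   concepts, a non-empty intersection of the domain sets is accepted;
   an empty intersection is flagged (*different domains with multiple focus
   concepts*). Overlap rather than equality was chosen because two clinical
   findings with additional ancillary domains should not be rejected.
4. **Per-relation checks.** For each attribute relation the set of domains
   whose own rule admits the (attribute, value) pair is computed. If it
   meets the focus domains, the relation is fine. Otherwise a three-way,
   mutually exclusive decision applies: admitted in some other domain →
   *invalid domain* (the relation is semantically correct, the focus
   concept is not); attribute known in the focus domains but value outside
   the range → *invalid attribute value*; anything else → *invalid
   attribute*. A nested-expression value satisfies a range iff **each** of
   its focus concepts satisfies the range ECL — the conservative reading of
   subsumption for expression values. Nested expressions are otherwise not
   recursively domain-checked; their concept references still pass stage 2.
5. **Cardinality.** Occurrences per attribute are counted across the whole
   expression against the attribute cardinality (both bounds) and within
   each role group against the in-group maximum. In-group minima are not
   enforced: released concept-model templates effectively always use an
   in-group minimum of 0, and a per-group minimum has no agreed semantics
   for groups the attribute never enters. Role-group *count* cardinality
   (how many groups an expression may carry) is likewise not enforced.
6. **Grouping requirement.** An ungrouped relation whose rule demands
   grouping is an *incorrect grouping* finding.

Issues are ordered by span start, making validation deterministic; a result
is valid iff it has no issues. Severity is not modeled — every finding is an
error.

## Terminology snapshot

The snapshot is an RF2-dialect trio of TSV files (concepts, IS-A
relationships, historical associations) plus an MRCM domain-refset TSV.
IS-A is the only relationship type consumed — the semantic checks rest on
the concept model, not on stated relationships. Inactive concepts are
retained with their hierarchy position. Historical resolution prefers SAME
AS over REPLACED BY (semantic equivalence is the stronger claim), orders
multiple targets by ascending id, and never follows replacement chains: a
replacement that is itself inactive is reported for manual resolution
instead.

ECL evaluation mirrors value-set expansion semantics: inactive concepts
never appear in `<<`/`<` results. The membership test used by the validator
waives the activity filter (`active_only=False`) so that an inactivated
code still resolves its domain and range — inactivity is reported by its
own category, not by knock-on range failures. `^ memberOf` returns matching
refset entries regardless of the referenced component's activity, because
resolving inactivated codes is exactly its purpose.

## Concept-model templates

The MRCM template dialect implemented is the minimal one the domain refset
needs for postcoordination: `[[m..n]]` cardinality markers (`*` unbounded),
`[[+id(ECL)]]` and `[[+scg(ECL)]]` range slots, one optional `{...}` group
block, comma-separated slots. A marker on a grouped slot is the in-group
cardinality (the attribute cardinality defaults to `0..*`); on an ungrouped
slot it is the attribute cardinality. Defaults when markers are absent:
attribute `0..*`, in-group `0..1`. Range ECL is stored verbatim and parsed
lazily on first use, so templates whose ranges use unsupported ECL features
only fail if those ranges are actually consulted. `parentDomain`
inheritance and multi-group templates are not implemented; every fixture
domain is self-contained. When several domains contribute a rule for the
same attribute, the merged rule takes the most permissive cardinalities and
requires grouping only if every contributing domain does; range admission is
always computed per-domain, so ranges are never merged.

## Correction suggestions

Suggestions are pure functions of (issue, snapshot, model): identical inputs
yield identical output. Replacement edits are validated at construction —
an edit is only attached if applying it yields text the parser accepts — so
the bracket- and character-repair categories generate candidate edits
(deletion, insertion, replacement with each plausible separator) and keep
the parseable ones rather than relying on per-case heuristics.

Category-specific behavior worth noting:

* *Invalid attribute*: candidates are the focus domains' attributes whose
  range admits the current value. Each substitution is revalidated;
  candidates that leave residual errors (e.g. a cardinality collision with
  an existing relation) rank last, then ranking is by term-token overlap
  with the original `|term|` text, then ascending id. Usage-frequency
  ranking ("this attribute is typically used with allergies") would need
  corpus statistics that a local snapshot does not carry and is not
  implemented.
* *Invalid attribute value*: alternatives are the nearest IS-A relatives of
  the current value (≤ 2 steps up or down, at most 10 shown) that fall
  inside the range — locality preserves intended meaning.
* *Syntactically incorrect code*: up to 50 active concepts containing the
  unresolvable digit sequence are substituted and fully revalidated; only
  cleanly revalidating candidates survive. This revalidation filter is the
  category's defining step.
* *Cardinality violation*: a surplus grouped relation is moved to a new role
  group, a surplus ungrouped relation is deleted (both as whole-expression
  rewrites through the canonical serializer, which guarantees
  parseability); a minimum violation is advisory only, since inventing an
  attribute value would be guesswork.
* When an inactivity finding and a semantic finding touch the same stretch
  of source, only the inactivity suggestion keeps its replacement edit; the
  semantic picture is re-derived after the replacement. This avoids
  conflicting edits on one span.

`apply_and_revalidate` applies rank-1 edits in descending span order
(offsets stay valid), skips overlapping edits, and revalidates once.
Iterating to a fixpoint is deliberately the caller's choice: the tool
suggests, the user decides.

Canonical serialization (used for batch deduplication) sorts focus
concepts, relations, and groups by id, normalizes whitespace, and preserves
terms; parse → serialize → parse is a fixed point on canonical forms.

## Synthetic data and what the tests show

The fixture snapshot is a ~70-concept synthetic edition: the handful of real
SNOMED CT identifiers needed by the worked examples (the metal-allergy
expression and its invalid-attribute variant, the inactivated environment
concept with its REPLACED BY successor, the Causative agent / Associated
with / Has realization / Method / Laterality attributes and well-known
hierarchy roots), embedded in filler concepts whose identifiers live in a
reserved `99`-prefixed range so they cannot collide with real SCTIDs. Three
domains (clinical finding, procedure, body structure) carry concept-model
rules chosen to exercise every check: grouped and ungrouped attributes, a
mandatory attribute (`Method`, `1..1`), in-group maxima, an `OR`-composed
expression-value range. Snapshot construction is fully deterministic
(byte-identical across runs).

The corpus generator builds valid expressions by sampling a domain, a focus
concept, and rule-conformant relations, then derives each invalid
expression from a fresh valid one by exactly one category-specific mutation
operator (attribute→non-attribute swap, out-of-range value, out-of-domain
focus, disjoint second focus, bracket deletion/duplication or un-grouping,
inactive-concept substitution, id truncation, relation duplication/removal
against cardinality, separator corruption). Every mutant is checked against
the validator during generation and resampled on spillover, so the injected
label is the single category the mutant triggers. Generation depends only
on (spec, snapshot, seed).

Default problem sizes — 450 mutants (50 per category) plus 50 valid
expressions for the completeness run, 200 random constraints of depth ≤ 3
for the ECL oracle, 60 bracket mutants for the repair check — were chosen
as the smallest sizes at which every mutation operator and evaluator branch
is exercised many times over; the whole suite runs in seconds.

What passing these tests does **not** show: fidelity to the full SNOMED CT
release. The fixture hierarchy is three levels deep where the real one is
dozens; real MRCM ranges use ECL features (refinements, wildcards, reverse
attributes) outside the implemented subset; real expressions carry
description-logic subtleties (normal forms, proximal primitives) that this
tool does not model. The properties demonstrated are of the *algorithms* —
category disjointness, single-error completeness, oracle equivalence,
round-trip stability, repair parseability — not of any particular release's
content.

## Numerical and degenerate-input choices

* Spans are half-open `[start, end)` 0-based character offsets; an empty
  input yields a single empty-construct finding at offset 0.
* Ties in issue ordering (same span start) break by category code, keeping
  reports deterministic.
* Duplicate identical relations are preserved by the parser — cardinality
  counting needs them.
* Term text inside `|...|` is never required to match the snapshot: the
  tool validates codes, not labels.
* The expression-level minimum-cardinality check anchors its finding to the
  whole-expression span, since there is no offending character to point at.

## Known limitations

* ECL subset only (self, `<<`, `<`, `OR`, `AND`, parentheses, `^` with
  selector and one member filter); no refinements, cardinality constraints,
  wildcards, or nested filters.
* One role-group block per MRCM template; no `parentDomain` inheritance.
* Replacement chains through successively inactivated concepts are flagged,
  not resolved.
* Suggestions are single-edit; expressions with many interacting errors may
  need several suggest→apply→revalidate rounds.
* FHIR input is read structurally as JSON (R4 Questionnaire / ValueSet /
  ConceptMap); resources are not schema-validated, and XML FHIR is out of
  scope.
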