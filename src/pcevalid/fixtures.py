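"""Miniature terminology snapshot and labeled expression corpora.

The fixture snapshot is a synthetic, desk-scale edition: it contains the
handful of real SNOMED CT concepts needed for the tool's worked examples
(the metal-allergy expression, the inactivated environment concept and its
replacement, the Causative agent / Associated with / Has realization
attributes) embedded in a synthetic hierarchy of filler concepts whose ids
live in a reserved ``99``-prefixed range so they can never collide with real
SCTIDs. It makes no claim of statistical realism about the full SNOMED CT
hierarchy.

:func:`generate_corpus` produces randomized valid expressions plus invalid
mutants, each mutant built from a valid expression by exactly one
category-specific mutation operator and checked against the validator during
generation (resampling on spillover), so the injected label is the single
category the expression triggers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import mrcm, validator as validator_mod
from .terminology import (
    REPLACED_BY_REFSET,
    ROOT_CONCEPT,
    SAME_AS_REFSET,
    TerminologyGraph,
    load_snapshot,
)
from .validator import IssueCode, validate

CLINICAL_FINDING = "404684003"
SUBSTANCE = "105590001"
PROCEDURE = "71388002"
BODY_STRUCTURE = "123037004"
QUALIFIER_VALUE = "362981000"
CONCEPT_MODEL_ATTRIBUTE = "410662002"
ENVIRONMENT = "308916002"
CAUSATIVE_AGENT = "246075003"
ASSOCIATED_WITH = "47429007"
HAS_REALIZATION = "719722006"
METHOD = "260686004"
LATERALITY = "272741003"
ACTION = "129264002"
ALLERGIC_PROCESS = "472964009"
ALLERGY_TO_METAL = "1155942004"
COBALT_CHROMIUM = "256526003"
UNFAMILIAR_ENV_OLD = "224799004"  # inactive
UNFAMILIAR_ENV_NEW = "1186687002"
SIDE = "990100101"

#: The well-formed metal-allergy expression used throughout docs and tests.
INTRO_EXPRESSION = (
    "1155942004 |Allergy to metal and/or metal compound|: "
    "{719722006 |Has realization| = 472964009 |Allergic process|, "
    "246075003 |Causative agent| = 256526003 |Cobalt-chromium alloy|}"
)

#: The same expression with Allergic process misused as an attribute.
INVALID_ATTRIBUTE_EXPRESSION = (
    "1155942004 |Allergy to metal and/or metal compound|: "
    "{719722006 |Has realization| = 472964009 |Allergic process|, "
    "472964009 |Allergic process| = 256526003 |Cobalt-chromium alloy|}"
)


def _concept_rows() -> list[tuple[str, str, str, list[str]]]:
    """(id, term, active, parents) rows for the fixture snapshot."""
    rows: list[tuple[str, str, str, list[str]]] = [
        (ROOT_CONCEPT, "SNOMED CT Concept", "1", []),
        (CLINICAL_FINDING, "Clinical finding", "1", [ROOT_CONCEPT]),
        (SUBSTANCE, "Substance", "1", [ROOT_CONCEPT]),
        (PROCEDURE, "Procedure", "1", [ROOT_CONCEPT]),
        (BODY_STRUCTURE, "Body structure", "1", [ROOT_CONCEPT]),
        (QUALIFIER_VALUE, "Qualifier value", "1", [ROOT_CONCEPT]),
        (CONCEPT_MODEL_ATTRIBUTE, "Concept model attribute", "1", [ROOT_CONCEPT]),
        (ENVIRONMENT, "Environment or geographical location", "1", [ROOT_CONCEPT]),
        (SAME_AS_REFSET, "SAME AS association reference set", "1", [ROOT_CONCEPT]),
        (REPLACED_BY_REFSET, "REPLACED BY association reference set", "1", [ROOT_CONCEPT]),
        (CAUSATIVE_AGENT, "Causative agent", "1", [CONCEPT_MODEL_ATTRIBUTE]),
        (ASSOCIATED_WITH, "Associated with", "1", [CONCEPT_MODEL_ATTRIBUTE]),
        (HAS_REALIZATION, "Has realization", "1", [CONCEPT_MODEL_ATTRIBUTE]),
        (METHOD, "Method", "1", [CONCEPT_MODEL_ATTRIBUTE]),
        (LATERALITY, "Laterality", "1", [CONCEPT_MODEL_ATTRIBUTE]),
        (ACTION, "Action", "1", [QUALIFIER_VALUE]),
        (ALLERGIC_PROCESS, "Allergic process", "1", [QUALIFIER_VALUE]),
        (UNFAMILIAR_ENV_NEW, "Unfamiliar environment (finding)", "1", [CLINICAL_FINDING]),
        (UNFAMILIAR_ENV_OLD, "Unfamiliar environment (environment)", "0", [ENVIRONMENT]),
        # substances (synthetic fillers below the real Substance root)
        ("990500101", "Metal (synthetic)", "1", [SUBSTANCE]),
        ("990500102", "Metal alloy (synthetic)", "1", ["990500101"]),
        (COBALT_CHROMIUM, "Cobalt-chromium alloy", "1", ["990500102"]),
        ("990500103", "Titanium-like metal (synthetic)", "1", ["990500101"]),
        ("990500104", "Nickel-like metal (synthetic)", "1", ["990500101"]),
        ("990500105", "Steel-like alloy (synthetic)", "1", ["990500102"]),
        ("990500106", "Bronze-like alloy (synthetic)", "1", ["990500102"]),
        ("990500107", "Polymer substance (synthetic)", "1", [SUBSTANCE]),
        ("990500108", "Latex-like substance (synthetic)", "1", [SUBSTANCE]),
        ("990500109", "Legacy alloy (synthetic, inactive)", "0", ["990500102"]),
        ("990500110", "Legacy substance (synthetic, inactive)", "0", [SUBSTANCE]),
        ("990500111", "Superseded metal (synthetic, inactive)", "0", ["990500101"]),
        # clinical findings
        ("990400101", "Allergy-type finding (synthetic)", "1", [CLINICAL_FINDING]),
        (ALLERGY_TO_METAL, "Allergy to metal and/or metal compound", "1", ["990400101"]),
        ("990400102", "Contact allergy-like finding (synthetic)", "1", ["990400101"]),
        ("990400103", "Injury-like finding (synthetic)", "1", [CLINICAL_FINDING]),
        ("990400104", "Inflammation-like finding (synthetic)", "1", [CLINICAL_FINDING]),
        ("990400105", "Dermatitis-like finding (synthetic)", "1", ["990400104"]),
        ("990400106", "Legacy finding (synthetic, inactive)", "0", [CLINICAL_FINDING]),
        ("990400107", "Pain-like finding (synthetic)", "1", [CLINICAL_FINDING]),
        ("990400108", "Swelling-like finding (synthetic)", "1", ["990400104"]),
        # procedures
        ("990200101", "Imaging-like procedure (synthetic)", "1", [PROCEDURE]),
        ("990200102", "Excision-like procedure (synthetic)", "1", [PROCEDURE]),
        ("990200103", "Biopsy-like procedure (synthetic)", "1", ["990200102"]),
        ("990200104", "Scan-like procedure (synthetic)", "1", ["990200101"]),
        # body structures
        ("990300101", "Limb structure (synthetic)", "1", [BODY_STRUCTURE]),
        ("990300102", "Hand structure (synthetic)", "1", ["990300101"]),
        ("990300103", "Foot structure (synthetic)", "1", ["990300101"]),
        ("990300104", "Organ structure (synthetic)", "1", [BODY_STRUCTURE]),
        # qualifiers
        (SIDE, "Side (synthetic)", "1", [QUALIFIER_VALUE]),
        ("990100102", "Left-like side (synthetic)", "1", [SIDE]),
        ("990100103", "Right-like side (synthetic)", "1", [SIDE]),
        ("990100104", "Inspection-like action (synthetic)", "1", [ACTION]),
        ("990100105", "Removal-like action (synthetic)", "1", [ACTION]),
        ("990100106", "Process-like qualifier (synthetic)", "1", [QUALIFIER_VALUE]),
    ]
    # reserve-range fillers to give the randomized tests room
    for i in range(1, 11):
        rows.append((f"9907001{i:02d}", f"Reserve substance {i} (synthetic)", "1", [SUBSTANCE]))
    for i in range(1, 9):
        rows.append((f"9907002{i:02d}", f"Reserve finding {i} (synthetic)", "1", [CLINICAL_FINDING]))
    return rows


_ASSOCIATIONS = [
    (REPLACED_BY_REFSET, UNFAMILIAR_ENV_OLD, UNFAMILIAR_ENV_NEW),
    (SAME_AS_REFSET, "990500109", "990500105"),
    (REPLACED_BY_REFSET, "990500110", "990500107"),
    (SAME_AS_REFSET, "990500111", "990500103"),
    (REPLACED_BY_REFSET, "990500111", "990500104"),
    (REPLACED_BY_REFSET, "990400106", "990400103"),
]

_MRCM_ROWS = [
    # refsetId, domain (referencedComponentId), domainConstraint, template
    (
        "723561005",
        CLINICAL_FINDING,
        "<< 404684003 |Clinical finding|",
        "[[0..*]] { [[0..1]] 246075003 = [[+id(<< 105590001 |Substance|)]], "
        "[[0..1]] 719722006 = [[+id(<< 362981000 |Qualifier value|)]], "
        "[[0..2]] 47429007 = [[+scg(<< 404684003 |Clinical finding| OR "
        "<< 105590001 |Substance| OR << 71388002 |Procedure|)]] }",
    ),
    (
        "723561005",
        PROCEDURE,
        "<< 71388002 |Procedure|",
        "[[1..1]] 260686004 = [[+id(<< 129264002 |Action|)]]",
    ),
    (
        "723561005",
        BODY_STRUCTURE,
        "<< 123037004 |Body structure|",
        "[[0..1]] { [[0..1]] 272741003 = [[+id(<< 990100101 |Side (synthetic)|)]] }",
    ),
]


def build_fixture_snapshot(out_dir: str | Path) -> dict[str, Path]:
    """Write the RF2-dialect snapshot files; byte-identical across runs.

    Returns the paths keyed by ``concepts``, ``relationships``,
    ``associations``, ``mrcm``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "concepts": out_dir / "concepts.tsv",
        "relationships": out_dir / "relationships.tsv",
        "associations": out_dir / "associations.tsv",
        "mrcm": out_dir / "mrcm.tsv",
    }
    rows = _concept_rows()
    with open(paths["concepts"], "w", newline="", encoding="utf-8") as handle:
        handle.write("id\tterm\tactive\n")
        for cid, term, active, _parents in rows:
            handle.write(f"{cid}\t{term}\t{active}\n")
    with open(paths["relationships"], "w", newline="", encoding="utf-8") as handle:
        handle.write("sourceId\tdestinationId\n")
        for cid, _term, _active, parents in rows:
            for parent in parents:
                handle.write(f"{cid}\t{parent}\n")
    with open(paths["associations"], "w", newline="", encoding="utf-8") as handle:
        handle.write("refsetId\treferencedComponentId\ttargetComponentId\n")
        for refset, referenced, target in _ASSOCIATIONS:
            handle.write(f"{refset}\t{referenced}\t{target}\n")
    with open(paths["mrcm"], "w", newline="", encoding="utf-8") as handle:
        handle.write(
            "refsetId\treferencedComponentId\tdomainConstraint\t"
            "domainTemplateForPostcoordination\n"
        )
        for refset, domain, constraint, template in _MRCM_ROWS:
            handle.write(f"{refset}\t{domain}\t{constraint}\t{template}\n")
    return paths


def load_fixture(out_dir: str | Path) -> tuple[TerminologyGraph, mrcm.ProcessedConceptModel]:
    """Load a built fixture snapshot and register the MRCM attribute set."""
    out_dir = Path(out_dir)
    graph = load_snapshot(
        out_dir / "concepts.tsv",
        out_dir / "relationships.tsv",
        out_dir / "associations.tsv",
    )
    model = mrcm.load_mrcm(out_dir / "mrcm.tsv")
    graph.attribute_ids = set(model.all_attributes)
    return graph, model


# ---------------------------------------------------------------------------
# corpus generation

@dataclass(frozen=True)
class CorpusSpec:
    n_valid: int
    per_category_counts: dict[IssueCode, int] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class LabeledExpression:
    text: str
    injected: Optional[IssueCode]  # None => validates cleanly
    provenance: str


class _Pools:
    """Deterministically ordered concept pools for sampling."""

    def __init__(self, graph: TerminologyGraph, model: mrcm.ProcessedConceptModel):
        self.graph = graph
        self.model = model
        down = lambda c: sorted(graph.descendants(c, active_only=True))
        self.findings = down(CLINICAL_FINDING)
        self.substances = down(SUBSTANCE)
        self.procedures = down(PROCEDURE)
        self.body = down(BODY_STRUCTURE)
        self.qualifiers = down(QUALIFIER_VALUE)
        self.actions = down(ACTION)
        self.sides = down(SIDE)
        attrs = model.all_attributes
        self.non_attributes = sorted(
            set(self.findings) | set(self.qualifiers) - attrs
        )
        self.inactive_substances = sorted(
            graph.descendants(SUBSTANCE, active_only=False)
            - set(self.substances)
        )
        self.inactive_findings = sorted(
            graph.descendants(CLINICAL_FINDING, active_only=False)
            - set(self.findings)
        )


class _Builder:
    """One valid expression as structure + renderer, so mutations can act on
    either the structure or the rendered text."""

    def __init__(self, rng: random.Random, pools: _Pools):
        self.rng = rng
        self.pools = pools
        self.graph = pools.graph
        self.domain = None  # set by build_*
        self.focus: list[str] = []
        self.ungrouped: list[tuple[str, str]] = []
        self.groups: list[list[tuple[str, str]]] = []

    def build(self, domain: str) -> "_Builder":
        rng, pools = self.rng, self.pools
        self.domain = domain
        if domain == CLINICAL_FINDING:
            self.focus = [rng.choice(pools.findings)]
            relations = []
            choices = rng.sample(["ca", "hr", "aw"], k=rng.randint(1, 3))
            for kind in sorted(choices):  # stable build order
                if kind == "ca":
                    relations.append((CAUSATIVE_AGENT, rng.choice(pools.substances)))
                elif kind == "hr":
                    relations.append((HAS_REALIZATION, rng.choice(pools.qualifiers)))
                else:
                    relations.append(
                        (
                            ASSOCIATED_WITH,
                            rng.choice(
                                pools.findings + pools.substances + pools.procedures
                            ),
                        )
                    )
            self.groups = [relations]
        elif domain == PROCEDURE:
            self.focus = [rng.choice(pools.procedures)]
            self.ungrouped = [(METHOD, rng.choice(pools.actions))]
        else:  # body structure
            self.focus = [rng.choice(pools.body)]
            self.groups = [[(LATERALITY, rng.choice(pools.sides))]]
        return self

    def _ref(self, cid: str) -> str:
        if self.rng.random() < 0.6 and cid in self.graph:
            return f"{cid} |{self.graph.term(cid)}|"
        return cid

    def render(self) -> str:
        sep = " " if self.rng.random() < 0.8 else "  "
        parts = [" + ".join(self._ref(f) for f in self.focus)]
        refinement = [f"{self._ref(a)} = {self._ref(v)}" for a, v in self.ungrouped]
        for group in self.groups:
            inner = ", ".join(f"{self._ref(a)} = {self._ref(v)}" for a, v in group)
            refinement.append("{" + sep + inner + sep + "}")
        text = parts[0]
        if refinement:
            text += sep + ":" + sep + ", ".join(refinement)
        return text

    def relations(self) -> list[tuple[int, int, tuple[str, str]]]:
        """(group_index or -1, position, (attr, value)) for every relation."""
        out = [(-1, i, rel) for i, rel in enumerate(self.ungrouped)]
        for g, group in enumerate(self.groups):
            out.extend((g, i, rel) for i, rel in enumerate(group))
        return out


def _truncate_unknown(cid: str, graph: TerminologyGraph) -> Optional[str]:
    candidate = cid[:-1]
    while len(candidate) >= 6:
        if candidate not in graph:
            return candidate
        candidate = candidate[:-1]
    return None


def _mutate(
    builder: _Builder, category: IssueCode, rng: random.Random, pools: _Pools
) -> Optional[tuple[str, str]]:
    """Apply the category's mutation; returns (mutant text, provenance)."""
    graph = builder.graph
    if category == IssueCode.INVALID_ATTRIBUTE:
        group_idx, pos, (attr, value) = rng.choice(builder.relations())
        fake = rng.choice(pools.non_attributes)
        if group_idx == -1:
            builder.ungrouped[pos] = (fake, value)
        else:
            builder.groups[group_idx][pos] = (fake, value)
        return builder.render(), f"attribute {attr} -> non-attribute {fake}"
    if category == IssueCode.INVALID_ATTRIBUTE_VALUE:
        group_idx, pos, (attr, value) = rng.choice(builder.relations())
        wrong = rng.choice(pools.body)
        if wrong == value:
            return None
        if group_idx == -1:
            builder.ungrouped[pos] = (attr, wrong)
        else:
            builder.groups[group_idx][pos] = (attr, wrong)
        return builder.render(), f"value {value} -> out-of-range {wrong}"
    if category == IssueCode.INVALID_DOMAIN:
        old = builder.focus[0]
        builder.focus[0] = rng.choice(pools.substances)
        return builder.render(), f"focus {old} -> out-of-domain {builder.focus[0]}"
    if category == IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH:
        extra_pool = {
            CLINICAL_FINDING: pools.body,
            BODY_STRUCTURE: pools.findings,
            PROCEDURE: pools.findings,
        }[builder.domain]
        extra = rng.choice(extra_pool)
        builder.focus.append(extra)
        return builder.render(), f"added focus {extra} from a disjoint domain"
    if category == IssueCode.GROUPING_ERROR:
        if not builder.groups:
            return None
        text = builder.render()
        mode = rng.choice(["drop_open", "drop_close", "dup_close", "ungroup"])
        if mode == "ungroup":
            group = builder.groups.pop(0)
            builder.ungrouped.extend(group)
            return builder.render(), "moved grouped relations out of their role group"
        if mode == "drop_open":
            i = text.index("{")
            return text[:i] + text[i + 1 :], "deleted an opening brace"
        if mode == "drop_close":
            i = text.rindex("}")
            return text[:i] + text[i + 1 :], "deleted a closing brace"
        i = text.rindex("}")
        return text[: i + 1] + "}" + text[i + 1 :], "duplicated a closing brace"
    if category == IssueCode.INACTIVE_CONCEPT:
        if builder.domain == CLINICAL_FINDING and rng.random() < 0.5:
            old = builder.focus[0]
            builder.focus[0] = rng.choice(pools.inactive_findings)
            return builder.render(), f"focus {old} -> inactive {builder.focus[0]}"
        targets = [
            (g, p, rel)
            for g, p, rel in builder.relations()
            if rel[0] == CAUSATIVE_AGENT
        ]
        if not targets:
            return None
        group_idx, pos, (attr, value) = rng.choice(targets)
        inactive = rng.choice(pools.inactive_substances)
        if group_idx == -1:
            builder.ungrouped[pos] = (attr, inactive)
        else:
            builder.groups[group_idx][pos] = (attr, inactive)
        return builder.render(), f"value {value} -> inactive {inactive}"
    if category == IssueCode.MALFORMED_SCTID:
        text = builder.render()
        all_ids = [f for f in builder.focus] + [
            v for _, _, (a, v) in builder.relations()
        ]
        cid = rng.choice(all_ids)
        truncated = _truncate_unknown(cid, graph)
        if truncated is None or cid not in text:
            return None
        mutant = text.replace(cid, truncated, 1)
        return mutant, f"truncated {cid} -> {truncated}"
    if category == IssueCode.CARDINALITY_VIOLATION:
        if builder.domain == PROCEDURE:
            if rng.random() < 0.5 and builder.ungrouped:
                builder.ungrouped.append(builder.ungrouped[0])
                return builder.render(), "duplicated the Method relation (max 1)"
            builder.ungrouped = []
            return builder.render(), "removed the mandatory Method relation (min 1)"
        targets = [
            (g, p, rel)
            for g, p, rel in builder.relations()
            if g >= 0 and rel[0] in (CAUSATIVE_AGENT, HAS_REALIZATION, LATERALITY)
        ]
        if not targets:
            return None
        group_idx, _pos, rel = rng.choice(targets)
        builder.groups[group_idx].append(rel)
        return builder.render(), f"duplicated {rel[0]} within its role group"
    if category == IssueCode.SYNTAX_CHAR_ERROR:
        text = builder.render()
        if rng.random() < 0.5 and ":" in text:
            i = text.index(":")
            return text[: i + 1] + "@" + text[i + 1 :], 'inserted "@" after ":"'
        if "," in text:
            i = text.index(",")
            return text[:i] + ";" + text[i + 1 :], 'replaced "," with ";"'
        return None
    raise ValueError(f"no mutation operator for {category}")


#: Domains a category's mutation operator can act on without side effects.
_CATEGORY_DOMAINS = {
    IssueCode.INVALID_ATTRIBUTE: [CLINICAL_FINDING, BODY_STRUCTURE],
    IssueCode.INVALID_ATTRIBUTE_VALUE: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
    IssueCode.INVALID_DOMAIN: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
    IssueCode.MULTI_FOCUS_DOMAIN_MISMATCH: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
    IssueCode.GROUPING_ERROR: [CLINICAL_FINDING, BODY_STRUCTURE],
    IssueCode.INACTIVE_CONCEPT: [CLINICAL_FINDING],
    IssueCode.MALFORMED_SCTID: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
    IssueCode.CARDINALITY_VIOLATION: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
    IssueCode.SYNTAX_CHAR_ERROR: [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE],
}

_ALL_DOMAINS = [CLINICAL_FINDING, PROCEDURE, BODY_STRUCTURE]


class CorpusGenerationError(Exception):
    pass


def generate_corpus(
    spec: CorpusSpec,
    graph: TerminologyGraph,
    model: mrcm.ProcessedConceptModel,
) -> list[LabeledExpression]:
    """Seeded, reproducible corpus of valid expressions and single-error mutants."""
    rng = random.Random(spec.seed)
    pools = _Pools(graph, model)
    out: list[LabeledExpression] = []

    for i in range(spec.n_valid):
        for _attempt in range(100):
            builder = _Builder(rng, pools).build(rng.choice(_ALL_DOMAINS))
            text = builder.render()
            if validate(text, graph, model).valid:
                out.append(LabeledExpression(text, None, f"valid sample {i}"))
                break
        else:
            raise CorpusGenerationError("could not build a valid expression")

    for category in sorted(spec.per_category_counts, key=lambda c: c.value):
        count = spec.per_category_counts[category]
        for i in range(count):
            for _attempt in range(100):
                domain = rng.choice(_CATEGORY_DOMAINS[category])
                builder = _Builder(rng, pools).build(domain)
                base = builder.render()
                if not validate(base, graph, model).valid:
                    continue
                mutated = _mutate(builder, category, rng, pools)
                if mutated is None:
                    continue
                text, provenance = mutated
                result = validate(text, graph, model)
                codes = {issue.code for issue in result.issues}
                if codes == {category}:
                    out.append(LabeledExpression(text, category, provenance))
                    break
            else:
                raise CorpusGenerationError(
                    f"could not inject a clean {category.value} mutant"
                )
    return out


def export_corpus_csv(corpus: list[LabeledExpression], out: str | Path) -> None:
    """Write the corpus in the CSV dialect the batch reader consumes
    (one expression per row, header ``expression``)."""
    import csv

    with open(out, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["expression"])
        for item in corpus:
            writer.writerow([item.text])
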