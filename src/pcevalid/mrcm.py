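"""Machine-Readable Concept Model: domain reference set and processed model.

SNOMED CT's Concept Model assigns every attribute a *domain* (which focus
concepts it may refine) and a *range* (which values it accepts), plus
cardinalities and grouping requirements. The MRCM Domain Reference Set ships
these rules as rows whose postcoordination *template* string — a
Compositional-Grammar-based dialect with ``[[...]]`` slot markers — encodes
the attributes, cardinalities, and value ranges of each domain.

This module decomposes those templates into a structured "processed concept
model" that every semantic check consumes directly, and round-trips it
to/from JSON.

Template dialect (one optional ``{...}`` group block per template):

* ``[[m..n]]`` cardinality markers, ``*`` for unbounded; on a grouped slot
  the marker is the in-group cardinality, on an ungrouped slot the attribute
  (whole-expression) cardinality
* ``[[+id(ECL)]]`` precoordinated-value range, ``[[+scg(ECL)]]``
  expression-value range, captured verbatim and parsed lazily on first use
* ``,``-separated attribute slots
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import ecl
from .terminology import TerminologyGraph


class MrcmError(Exception):
    pass


class TemplateParseError(MrcmError):
    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (offset {offset})")


class UnknownDomainError(MrcmError):
    def __init__(self, domain_id: str):
        self.domain_id = domain_id
        super().__init__(f"unknown domain id: {domain_id}")


@dataclass(frozen=True)
class Cardinality:
    """``min..max`` occurrence bounds; ``max=None`` means unbounded (``*``)."""

    min: int
    max: Optional[int]

    def __post_init__(self):
        if self.min < 0 or (self.max is not None and self.min > self.max):
            raise ValueError(f"invalid cardinality {self}")

    def allows(self, count: int) -> bool:
        return count >= self.min and (self.max is None or count <= self.max)

    def merge_permissive(self, other: "Cardinality") -> "Cardinality":
        max_ = None if self.max is None or other.max is None else max(self.max, other.max)
        return Cardinality(min(self.min, other.min), max_)

    def __str__(self) -> str:
        return f"{self.min}..{'*' if self.max is None else self.max}"

    @classmethod
    def parse(cls, text: str) -> "Cardinality":
        match = re.fullmatch(r"\s*(\d+)\.\.(\d+|\*)\s*", text)
        if match is None:
            raise ValueError(f"invalid cardinality text {text!r}")
        max_ = None if match.group(2) == "*" else int(match.group(2))
        return cls(int(match.group(1)), max_)


DEFAULT_ATTRIBUTE_CARDINALITY = Cardinality(0, None)
DEFAULT_IN_GROUP_CARDINALITY = Cardinality(0, 1)


@dataclass(frozen=True)
class AttributeRule:
    attribute: str
    range_constraint: str  # ECL text, parsed lazily
    attribute_cardinality: Cardinality
    in_group_cardinality: Cardinality
    grouped: bool  # attribute appears inside the template's group block
    range_kind: str = "id"  # "id" or "scg" slot marker


@dataclass(frozen=True)
class DomainRule:
    domain_id: str
    domain_constraint: str  # ECL text
    group_cardinality: Optional[Cardinality]
    rules: tuple[AttributeRule, ...]


class ProcessedConceptModel:
    """Per-domain attribute rules plus the global set of attribute concepts."""

    def __init__(self, domains: dict[str, DomainRule]):
        self.domains = dict(domains)
        self._ecl_cache: dict[str, ecl.EclNode] = {}

    @property
    def all_attributes(self) -> set[str]:
        return {
            rule.attribute
            for domain in self.domains.values()
            for rule in domain.rules
        }

    def constraint(self, text: str) -> ecl.EclNode:
        """Parse an embedded ECL fragment, caching by text."""
        node = self._ecl_cache.get(text)
        if node is None:
            node = ecl.parse_ecl(text)
            self._ecl_cache[text] = node
        return node


# ---------------------------------------------------------------------------
# template parsing

_MARKER_RE = re.compile(r"\[\[")


def _find_markers(text: str) -> list[tuple[int, int, str]]:
    """All ``[[...]]`` markers as (start, end, inner-text); nested parens in
    range markers are respected by matching the literal ``)]]`` / ``]]`` tail."""
    out = []
    pos = 0
    while True:
        match = _MARKER_RE.search(text, pos)
        if match is None:
            break
        start = match.start()
        end = text.find("]]", start)
        if end == -1:
            raise TemplateParseError("unmatched [[", start)
        out.append((start, end + 2, text[start + 2 : end]))
        pos = end + 2
    if text.find("]]", pos) != -1:
        raise TemplateParseError("unmatched ]]", text.find("]]", pos))
    return out


def _split_top_level(text: str, base_offset: int) -> list[tuple[str, int]]:
    """Split on commas outside ``[[...]]``, ``(...)`` and ``|...|``."""
    parts = []
    depth_paren = 0
    in_marker = False
    in_term = False
    current_start = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if in_term:
            if ch == "|":
                in_term = False
        elif in_marker:
            if text.startswith("]]", i):
                in_marker = False
                i += 2
                continue
        elif ch == "|":
            in_term = True
        elif text.startswith("[[", i):
            in_marker = True
            i += 2
            continue
        elif ch == "(":
            depth_paren += 1
        elif ch == ")":
            depth_paren -= 1
        elif ch == "," and depth_paren == 0:
            parts.append((text[current_start:i], base_offset + current_start))
            current_start = i + 1
        i += 1
    parts.append((text[current_start:], base_offset + current_start))
    return [(p, off) for p, off in parts if p.strip()]


_SLOT_RE = re.compile(
    r"^\s*(?:\[\[(?P<card>\d+\.\.(?:\d+|\*))\]\])?"
    r"\s*(?P<attr>\d+)\s*(?:\|(?P<term>[^|]*)\|)?"
    r"\s*=\s*\[\[\+(?P<kind>id|scg)\((?P<range>.*)\)\]\]\s*$",
    re.DOTALL,
)


def _parse_slot(text: str, offset: int, grouped: bool) -> AttributeRule:
    match = _SLOT_RE.match(text)
    if match is None:
        raise TemplateParseError(f"malformed attribute slot {text.strip()!r}", offset)
    try:
        card = (
            Cardinality.parse(match.group("card"))
            if match.group("card")
            else None
        )
    except ValueError as exc:
        raise TemplateParseError(str(exc), offset) from None
    if grouped:
        attribute_cardinality = DEFAULT_ATTRIBUTE_CARDINALITY
        in_group = card or DEFAULT_IN_GROUP_CARDINALITY
    else:
        attribute_cardinality = card or DEFAULT_ATTRIBUTE_CARDINALITY
        in_group = DEFAULT_IN_GROUP_CARDINALITY
    return AttributeRule(
        attribute=match.group("attr"),
        range_constraint=match.group("range").strip(),
        attribute_cardinality=attribute_cardinality,
        in_group_cardinality=in_group,
        grouped=grouped,
        range_kind=match.group("kind"),
    )


def parse_template(
    template_text: str,
) -> tuple[Optional[Cardinality], list[AttributeRule]]:
    """Decompose a postcoordination template into group cardinality and rules."""
    _find_markers(template_text)  # surface unmatched [[ / ]] early
    brace_open = template_text.find("{")
    group_cardinality = None
    rules: list[AttributeRule] = []
    if brace_open != -1:
        brace_close = template_text.rfind("}")
        if brace_close == -1 or brace_close < brace_open:
            raise TemplateParseError("unmatched { in template", brace_open)
        before = template_text[:brace_open]
        inside = template_text[brace_open + 1 : brace_close]
        after = template_text[brace_close + 1 :]
        # a cardinality marker immediately before the block binds to the group
        card_match = re.search(r"\[\[(\d+\.\.(?:\d+|\*))\]\]\s*$", before)
        if card_match:
            try:
                group_cardinality = Cardinality.parse(card_match.group(1))
            except ValueError as exc:
                raise TemplateParseError(str(exc), card_match.start()) from None
            before = before[: card_match.start()]
        for part, offset in _split_top_level(before, 0):
            rules.append(_parse_slot(part, offset, grouped=False))
        for part, offset in _split_top_level(inside, brace_open + 1):
            rules.append(_parse_slot(part, offset, grouped=True))
        for part, offset in _split_top_level(after, brace_close + 1):
            rules.append(_parse_slot(part, offset, grouped=False))
    else:
        for part, offset in _split_top_level(template_text, 0):
            rules.append(_parse_slot(part, offset, grouped=False))
    if not rules:
        raise TemplateParseError("template defines no attribute slots", 0)
    return group_cardinality, rules


def render_template(
    group_cardinality: Optional[Cardinality], rules: list[AttributeRule]
) -> str:
    """Canonical template text; inverse of :func:`parse_template` (used by the
    round-trip property test and the fixture writer)."""

    def slot(rule: AttributeRule) -> str:
        card = (
            rule.in_group_cardinality if rule.grouped else rule.attribute_cardinality
        )
        return f"[[{card}]] {rule.attribute} = [[+{rule.range_kind}({rule.range_constraint})]]"

    ungrouped = [slot(r) for r in rules if not r.grouped]
    grouped = [slot(r) for r in rules if r.grouped]
    parts = []
    if ungrouped:
        parts.append(", ".join(ungrouped))
    if grouped:
        prefix = f"[[{group_cardinality}]] " if group_cardinality else ""
        parts.append(prefix + "{ " + ", ".join(grouped) + " }")
    return ", ".join(parts)


# ---------------------------------------------------------------------------
# refset loading and JSON round trip

def load_mrcm(path: str | Path) -> ProcessedConceptModel:
    """Load the MRCM domain refset (tab-separated: ``refsetId,
    referencedComponentId, domainConstraint, domainTemplateForPostcoordination``)."""
    import csv

    path = Path(path)
    if not path.exists():
        raise MrcmError(f"MRCM file not found: {path}")
    domains: dict[str, DomainRule] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = [
            "refsetId",
            "referencedComponentId",
            "domainConstraint",
            "domainTemplateForPostcoordination",
        ]
        if reader.fieldnames is None or any(
            col not in reader.fieldnames for col in required
        ):
            raise MrcmError(
                f"{path}: expected columns {required}, found {reader.fieldnames}"
            )
        for row in reader:
            domain_id = row["referencedComponentId"]
            group_card, rules = parse_template(
                row["domainTemplateForPostcoordination"]
            )
            domains[domain_id] = DomainRule(
                domain_id=domain_id,
                domain_constraint=row["domainConstraint"],
                group_cardinality=group_card,
                rules=tuple(rules),
            )
    return ProcessedConceptModel(domains)


def export_processed_model(model: ProcessedConceptModel, out: str | Path) -> None:
    """Write the processed model as JSON (top-level key ``domains``, stable
    key order, UTF-8); :func:`import_processed_model` round-trips it."""
    doc = {"domains": {}}
    for domain_id in sorted(model.domains):
        domain = model.domains[domain_id]
        doc["domains"][domain_id] = {
            "domainConstraint": domain.domain_constraint,
            "groupCardinality": (
                str(domain.group_cardinality) if domain.group_cardinality else None
            ),
            "attributes": [
                {
                    "attributeId": rule.attribute,
                    "rangeConstraint": rule.range_constraint,
                    "rangeKind": rule.range_kind,
                    "attributeCardinality": str(rule.attribute_cardinality),
                    "inGroupCardinality": str(rule.in_group_cardinality),
                    "grouped": rule.grouped,
                }
                for rule in domain.rules
            ],
        }
    with open(out, "w", encoding="utf-8") as handle:
        json.dump(doc, handle, indent=2, ensure_ascii=False, sort_keys=False)
        handle.write("\n")


def import_processed_model(path: str | Path) -> ProcessedConceptModel:
    with open(path, encoding="utf-8") as handle:
        doc = json.load(handle)
    domains = {}
    for domain_id, entry in doc["domains"].items():
        rules = tuple(
            AttributeRule(
                attribute=a["attributeId"],
                range_constraint=a["rangeConstraint"],
                attribute_cardinality=Cardinality.parse(a["attributeCardinality"]),
                in_group_cardinality=Cardinality.parse(a["inGroupCardinality"]),
                grouped=a["grouped"],
                range_kind=a.get("rangeKind", "id"),
            )
            for a in entry["attributes"]
        )
        domains[domain_id] = DomainRule(
            domain_id=domain_id,
            domain_constraint=entry["domainConstraint"],
            group_cardinality=(
                Cardinality.parse(entry["groupCardinality"])
                if entry["groupCardinality"]
                else None
            ),
            rules=rules,
        )
    return ProcessedConceptModel(domains)


def models_equal(a: ProcessedConceptModel, b: ProcessedConceptModel) -> bool:
    return a.domains == b.domains


# ---------------------------------------------------------------------------
# queries

def domains_of(
    concept: str,
    model: ProcessedConceptModel,
    graph: TerminologyGraph,
    active_only: bool = False,
) -> set[str]:
    """All domains whose constraint admits *concept*.

    By default inactivity does not strip a concept of its domain (the
    dedicated inactive-code category reports it instead), so domain analysis
    still works on expressions carrying inactivated codes.
    """
    out = set()
    for domain_id, domain in model.domains.items():
        node = model.constraint(domain.domain_constraint)
        if ecl.in_value_set(concept, node, graph, active_only=active_only):
            out.add(domain_id)
    return out


def rules_for(
    domain_ids: set[str], model: ProcessedConceptModel
) -> list[AttributeRule]:
    """Concatenated rules over the given domains, deduplicated by attribute.

    On a duplicate attribute the most permissive cardinalities win and
    grouping is only required when every contributing domain requires it; the
    first domain's range text is kept as representative (range admission is
    computed per-domain by the validator, not from the merged rule).
    """
    merged: dict[str, AttributeRule] = {}
    for domain_id in sorted(domain_ids):
        if domain_id not in model.domains:
            raise UnknownDomainError(domain_id)
        for rule in model.domains[domain_id].rules:
            existing = merged.get(rule.attribute)
            if existing is None:
                merged[rule.attribute] = rule
            else:
                merged[rule.attribute] = AttributeRule(
                    attribute=rule.attribute,
                    range_constraint=existing.range_constraint,
                    attribute_cardinality=existing.attribute_cardinality.merge_permissive(
                        rule.attribute_cardinality
                    ),
                    in_group_cardinality=existing.in_group_cardinality.merge_permissive(
                        rule.in_group_cardinality
                    ),
                    grouped=existing.grouped and rule.grouped,
                    range_kind=existing.range_kind,
                )
    return [merged[attr] for attr in sorted(merged)]
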