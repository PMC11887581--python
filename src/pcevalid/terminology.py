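"""In-memory SNOMED CT terminology snapshot.

The snapshot is the local stand-in for a terminology server's knowledge of an
edition: active/inactive concepts, the IS-A hierarchy, preferred terms, and
the historical-association reference sets that map inactivated concepts to
their active successors (SAME AS, REPLACED BY).

Files are an RF2-dialect set of tab-separated tables (see :func:`load_snapshot`);
full RF2 release fidelity (effectiveTime, moduleId, description files) is a
non-goal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

#: The SNOMED CT root concept, |SNOMED CT Concept|.
ROOT_CONCEPT = "138875005"
#: |SAME AS association reference set| — semantically equivalent active concept.
SAME_AS_REFSET = "900000000000527005"
#: |REPLACED BY association reference set| — active concept replacing an inactivated one.
REPLACED_BY_REFSET = "900000000000526001"


class TerminologyError(Exception):
    """Base error for terminology loading and lookup."""


class SnapshotLoadError(TerminologyError):
    """A snapshot file is missing or a row violates the column contract."""


class UnknownConceptError(TerminologyError):
    """A concept id was looked up that is not in the snapshot."""

    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"unknown concept id: {concept_id}")


def is_valid_sctid(value: str) -> bool:
    """True iff *value* is shaped like an SCTID: 6-18 decimal digits."""
    return value.isascii() and value.isdigit() and 6 <= len(value) <= 18


@dataclass(frozen=True)
class ConceptRecord:
    id: str
    term: str
    active: bool
    parents: frozenset[str]


@dataclass(frozen=True)
class AssociationEntry:
    """One historical-association refset row: inactive concept -> active target."""

    refset_id: str
    referenced_component: str
    target_component: str


class TerminologyGraph:
    """Concepts plus IS-A edges plus historical associations.

    IS-A is the only relationship type consumed; defining attribute
    relationships are out of scope (semantic checks use the MRCM instead).
    """

    def __init__(
        self,
        concepts: dict[str, ConceptRecord],
        associations: list[AssociationEntry] | None = None,
        attribute_ids: frozenset[str] = frozenset(),
    ):
        self.concepts = dict(concepts)
        self.associations = list(associations or [])
        self.attribute_ids = set(attribute_ids)
        self._isa = nx.DiGraph()  # edge child -> parent
        self._isa.add_nodes_from(self.concepts)
        for record in self.concepts.values():
            for parent in record.parents:
                if parent not in self.concepts:
                    raise SnapshotLoadError(
                        f"concept {record.id} has unknown parent {parent}"
                    )
                self._isa.add_edge(record.id, parent)
        if not nx.is_directed_acyclic_graph(self._isa):
            raise SnapshotLoadError("IS-A graph contains a cycle")
        for entry in self.associations:
            for endpoint in (entry.referenced_component, entry.target_component):
                if endpoint not in self.concepts:
                    raise SnapshotLoadError(
                        f"association endpoint {endpoint} not in snapshot"
                    )

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def record(self, concept_id: str) -> ConceptRecord:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def is_active(self, concept_id: str) -> bool:
        return self.record(concept_id).active

    def term(self, concept_id: str) -> str:
        return self.record(concept_id).term

    def descendants(self, concept_id: str, active_only: bool = True) -> set[str]:
        """All strict descendants of *concept_id* via IS-A."""
        self.record(concept_id)
        below = nx.ancestors(self._isa, concept_id)  # nodes that reach it
        if active_only:
            below = {c for c in below if self.concepts[c].active}
        return below

    def is_descendant_or_self(self, candidate: str, ancestor: str) -> bool:
        """True iff *candidate* == *ancestor* or *ancestor* is reachable via IS-A."""
        self.record(candidate)
        self.record(ancestor)
        if candidate == ancestor:
            return True
        return nx.has_path(self._isa, candidate, ancestor)

    def resolve_historical(self, inactive: str) -> list[tuple[str, str]]:
        """Historical-association targets for an (inactive) concept.

        Returns ``(refset_id, target_component)`` pairs, SAME AS entries
        before REPLACED BY entries (semantic equivalence is the stronger
        claim), ascending target id within a refset. Empty when no entry
        exists; replacement chains are never followed.
        """
        self.record(inactive)
        entries = [a for a in self.associations if a.referenced_component == inactive]
        order = {SAME_AS_REFSET: 0, REPLACED_BY_REFSET: 1}
        entries.sort(key=lambda a: (order.get(a.refset_id, 2), a.target_component))
        return [(a.refset_id, a.target_component) for a in entries]

    def find_ids_containing(self, digit_sequence: str) -> set[str]:
        """All *active* concept ids containing the digit sequence as a substring."""
        if not digit_sequence or not (
            digit_sequence.isascii() and digit_sequence.isdigit()
        ):
            raise ValueError(f"digit sequence required, got {digit_sequence!r}")
        return {
            cid
            for cid, rec in self.concepts.items()
            if rec.active and digit_sequence in cid
        }


def _read_rows(path: Path, required: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise SnapshotLoadError(f"snapshot file not found: {path}")
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or any(
            col not in reader.fieldnames for col in required
        ):
            raise SnapshotLoadError(
                f"{path}: expected columns {required}, found {reader.fieldnames}"
            )
        return list(reader)


def load_snapshot(
    concepts_file: str | Path,
    relationships_file: str | Path,
    associations_file: str | Path,
) -> TerminologyGraph:
    """Load an RF2-dialect snapshot.

    Column contracts (tab-separated, UTF-8, header row):

    * concepts: ``id, term, active`` with active in {0, 1}
    * relationships: ``sourceId, destinationId`` meaning source IS-A destination
    * associations: ``refsetId, referencedComponentId, targetComponentId``

    Inactive concepts are retained (with ``active=False``): they are needed to
    detect and repair inactivated codes.
    """
    concept_rows = _read_rows(Path(concepts_file), ["id", "term", "active"])
    rel_rows = _read_rows(Path(relationships_file), ["sourceId", "destinationId"])
    assoc_rows = _read_rows(
        Path(associations_file),
        ["refsetId", "referencedComponentId", "targetComponentId"],
    )

    parents: dict[str, set[str]] = {row["id"]: set() for row in concept_rows}
    for i, row in enumerate(rel_rows, start=2):
        src, dst = row["sourceId"], row["destinationId"]
        if src not in parents or dst not in parents:
            raise SnapshotLoadError(
                f"{relationships_file}: row {i} references unknown concept "
                f"({src} IS-A {dst})"
            )
        parents[src].add(dst)

    concepts = {}
    for row in concept_rows:
        cid = row["id"]
        concepts[cid] = ConceptRecord(
            id=cid,
            term=row["term"],
            active=row["active"] == "1",
            parents=frozenset(parents[cid]),
        )

    associations = []
    for i, row in enumerate(assoc_rows, start=2):
        entry = AssociationEntry(
            refset_id=row["refsetId"],
            referenced_component=row["referencedComponentId"],
            target_component=row["targetComponentId"],
        )
        if entry.referenced_component not in concepts:
            raise SnapshotLoadError(
                f"{associations_file}: row {i} references unknown concept "
                f"{entry.referenced_component}"
            )
        associations.append(entry)

    return TerminologyGraph(concepts, associations)


def save_snapshot(
    graph: TerminologyGraph,
    concepts_file: str | Path,
    relationships_file: str | Path,
    associations_file: str | Path,
) -> None:
    """Re-serialize a snapshot to the same RF2-dialect files, deterministically."""
    with open(concepts_file, "w", newline="", encoding="utf-8") as handle:
        handle.write("id\tterm\tactive\n")
        for cid in sorted(graph.concepts):
            rec = graph.concepts[cid]
            handle.write(f"{rec.id}\t{rec.term}\t{1 if rec.active else 0}\n")
    with open(relationships_file, "w", newline="", encoding="utf-8") as handle:
        handle.write("sourceId\tdestinationId\n")
        for cid in sorted(graph.concepts):
            for parent in sorted(graph.concepts[cid].parents):
                handle.write(f"{cid}\t{parent}\n")
    with open(associations_file, "w", newline="", encoding="utf-8") as handle:
        handle.write("refsetId\treferencedComponentId\ttargetComponentId\n")
        for a in sorted(
            graph.associations,
            key=lambda a: (a.refset_id, a.referenced_component, a.target_component),
        ):
            handle.write(
                f"{a.refset_id}\t{a.referenced_component}\t{a.target_component}\n"
            )
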