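"""Phenotype ontology: OBO parsing, DAG navigation and substring search.

The ontology is a directed acyclic graph of phenotype concepts (e.g. HPO
terms such as ``HP:0003540`` "Platelet aggregation defect") connected by
``is_a`` edges.  Only ``[Term]`` stanzas and the keys ``id``, ``name``,
``synonym``, ``is_a`` and ``is_obsolete`` are interpreted; everything else
in the file is ignored.  Obsolete terms are recorded but excluded from
navigation, search and downstream linking.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx

from .errors import (
    DanglingReferenceError,
    OboFormatError,
    ObsoleteConceptError,
    OntologyCycleError,
    UnknownConceptError,
)

__all__ = [
    "Concept",
    "Ontology",
    "parse_obo",
    "descendants",
    "ancestors",
    "search_concepts",
]


@dataclass
class Concept:
    """One ontology term.

    Parameters
    ----------
    id : str
        Accession of the form ``PREFIX:digits`` (``HP:0000709`` for real data).
    name : str
        Primary display label; nonempty for non-obsolete concepts.
    synonyms : list of str
        Alternative labels (possibly empty).
    parent_ids : list of str
        Accessions of the concept's ``is_a`` parents, without duplicates.
    obsolete : bool
        Obsolete terms are kept for bookkeeping but take no part in
        navigation, search or linking.
    """

    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    parent_ids: list[str] = field(default_factory=list)
    obsolete: bool = False


class Ontology:
    """A DAG of :class:`Concept` objects keyed by accession.

    The child relation is exactly the inverse of the parent relation.
    Construction validates that every parent id resolves and that the
    parent graph is acyclic.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if not c.id:
                raise OboFormatError("concept with empty id")
            if c.id in self.concepts:
                raise OboFormatError(f"duplicate term id: {c.id}")
            if not c.obsolete and not c.name:
                raise OboFormatError(f"non-obsolete term without a name: {c.id}")
            self.concepts[c.id] = c

        known = set(self.concepts)
        full = nx.DiGraph()  # parent -> child over *all* terms, for cycle check
        full.add_nodes_from(known)
        for c in self.concepts.values():
            seen: set[str] = set()
            deduped = []
            for p in c.parent_ids:
                if p not in known:
                    raise DanglingReferenceError(
                        f"term {c.id} references undefined parent {p}"
                    )
                if p not in seen:
                    seen.add(p)
                    deduped.append(p)
                full.add_edge(p, c.id)
            c.parent_ids = deduped

        try:
            cycle = nx.find_cycle(full, orientation="original")
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            path = [edge[0] for edge in cycle] + [cycle[-1][1]]
            raise OntologyCycleError(path)

        # navigation graph: parent -> child edges among non-obsolete terms only
        self.graph = nx.DiGraph()
        active = [c for c in self.concepts.values() if not c.obsolete]
        self.graph.add_nodes_from(c.id for c in active)
        for c in active:
            for p in c.parent_ids:
                if not self.concepts[p].obsolete:
                    self.graph.add_edge(p, c.id)
        self.roots: set[str] = {
            n for n in self.graph.nodes if self.graph.in_degree(n) == 0
        }

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(f"unknown concept id: {concept_id}") from None

    def is_active(self, concept_id: str) -> bool:
        """True when the id resolves to a non-obsolete concept."""
        c = self.concepts.get(concept_id)
        return c is not None and not c.obsolete

    def active_concepts(self) -> Iterable[Concept]:
        """Non-obsolete concepts in file order."""
        return (c for c in self.concepts.values() if not c.obsolete)

    def parents(self, concept_id: str) -> set[str]:
        self._require_active(concept_id)
        return set(self.graph.predecessors(concept_id))

    def children(self, concept_id: str) -> set[str]:
        self._require_active(concept_id)
        return set(self.graph.successors(concept_id))

    def _require_known(self, concept_id: str) -> Concept:
        if concept_id not in self.concepts:
            raise UnknownConceptError(f"unknown concept id: {concept_id}")
        return self.concepts[concept_id]

    def _require_active(self, concept_id: str) -> Concept:
        c = self._require_known(concept_id)
        if c.obsolete:
            raise ObsoleteConceptError(f"concept {concept_id} is obsolete")
        return c


def _extract_synonym(value: str) -> str | None:
    # OBO synonym lines quote the label: synonym: "Bruising" EXACT []
    if not value.startswith('"'):
        return value.split("!")[0].strip() or None
    end = value.find('"', 1)
    while end != -1 and value[end - 1] == "\\":
        end = value.find('"', end + 1)
    if end == -1:
        return None
    return value[1:end].replace('\\"', '"')


def parse_obo(stream: str | TextIO) -> Ontology:
    """Parse OBO 1.2-style flat text into an :class:`Ontology`.

    ``is_a`` targets are stripped of trailing ``! comment`` text.  Raises
    :class:`OboFormatError` for duplicate ids,
    :class:`DanglingReferenceError` for undefined ``is_a`` targets and
    :class:`OntologyCycleError` when the parent relation is cyclic.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    concepts: list[Concept] = []
    seen_ids: set[str] = set()
    current: dict | None = None
    in_term = False

    def flush():
        nonlocal current
        if current is None:
            return
        cid = current.get("id")
        if not cid:
            raise OboFormatError("[Term] stanza without an id")
        if cid in seen_ids:
            raise OboFormatError(f"duplicate term id: {cid}")
        seen_ids.add(cid)
        concepts.append(
            Concept(
                id=cid,
                name=current.get("name", ""),
                synonyms=current["synonyms"],
                parent_ids=current["parents"],
                obsolete=current.get("obsolete", False),
            )
        )
        current = None

    for raw in stream:
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            current = {"synonyms": [], "parents": []} if in_term else None
            continue
        if current is None or not line or line.startswith("!"):
            continue
        key, sep, value = line.partition(":")
        if not sep:
            continue
        key = key.strip()
        value = value.strip()
        if key == "id":
            current["id"] = value
        elif key == "name":
            current["name"] = value.split(" ! ")[0].strip()
        elif key == "synonym":
            syn = _extract_synonym(value)
            if syn:
                current["synonyms"].append(syn)
        elif key == "is_a":
            target = value.split("!")[0].strip()
            if target:
                current["parents"].append(target)
        elif key == "is_obsolete":
            current["obsolete"] = value.lower().startswith("true")
    flush()
    return Ontology(concepts)


def descendants(ontology: Ontology, concept_id: str) -> set[str]:
    """Ids reachable from ``concept_id`` via child edges, excluding itself."""
    ontology._require_active(concept_id)
    return set(nx.descendants(ontology.graph, concept_id))


def ancestors(ontology: Ontology, concept_id: str) -> set[str]:
    """Ids reachable from ``concept_id`` via parent edges, excluding itself."""
    c = ontology._require_known(concept_id)
    if c.obsolete or concept_id not in ontology.graph:
        return set()
    return set(nx.ancestors(ontology.graph, concept_id))


def search_concepts(ontology: Ontology, query: str) -> list[Concept]:
    """All non-obsolete concepts whose name or synonym contains ``query``.

    Matching is case-insensitive substring containment.  Results are ordered
    by (name length ascending, id) so the most specific match leads.  A query
    that is empty after trimming raises ``ValueError`` rather than matching
    everything.
    """
    q = query.strip().lower()
    if not q:
        raise ValueError("search query must be non-empty")
    hits = [
        c
        for c in ontology.active_concepts()
        if q in c.name.lower() or any(q in s.lower() for s in c.synonyms)
    ]
    hits.sort(key=lambda c: (len(c.name), c.id))
    return hits
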