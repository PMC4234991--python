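"""Association tables, concept-association links and the SQLite knowledge base.

The knowledge base combines a phenotype ontology with genetic-association
records from heterogeneous catalogues (a GAD-style table carrying free-text
phenotype descriptions, a GWASdb-style table accompanied by a precomputed
phenotype-to-concept mapping) and the many-to-many links between them.
"""

from __future__ import annotations

import csv
import enum
import io
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, TextIO

import pandas as pd

from .errors import IntegrityError, StorageError, TableFormatError
from .ontology import Concept, Ontology

__all__ = [
    "Source",
    "AssociationRecord",
    "AssociationTable",
    "Link",
    "LinkSet",
    "MappingReport",
    "KnowledgeBase",
    "read_association_table",
    "import_mapping",
    "build_knowledgebase",
    "persist_kb",
    "load_kb",
    "write_obo",
]


class Source(str, enum.Enum):
    """Origin catalogue of an association record."""

    GAD = "GAD"
    GWASDB = "GWASDB"
    OTHER = "OTHER"


@dataclass
class AssociationRecord:
    """One gene-phenotype association from a named source.

    Gene symbols are uppercased for identity; ``pvalue`` (when present) is
    the association p-value reported by the source, in (0, 1].
    """

    record_id: str
    gene: str
    phenotype_text: str
    source: Source
    pvalue: float | None = None
    variant_id: str | None = None


@dataclass
class AssociationTable:
    """Ordered records sharing one source, plus the count of dropped rows."""

    records: list[AssociationRecord]
    source: Source
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)


class Link(NamedTuple):
    """A concept <-> association pairing with provenance."""

    concept_id: str
    record_id: str
    provenance: str  # "matched" (text index) or "imported" (precomputed map)


class LinkSet:
    """A set of links, unique on the (concept_id, record_id) pair.

    ``source`` optionally records which table's record-id space the links
    refer to, so that :func:`build_knowledgebase` can remap ids when record
    ids collide across tables.
    """

    def __init__(self, links: Iterable[Link] = (), source: Source | None = None):
        self._by_pair: dict[tuple[str, str], str] = {}
        self.source = source
        for link in links:
            self.add(*link)

    def add(self, concept_id: str, record_id: str, provenance: str) -> None:
        self._by_pair.setdefault((concept_id, record_id), provenance)

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self):
        for (cid, rid), prov in self._by_pair.items():
            yield Link(cid, rid, prov)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair[:2]) in self._by_pair

    def __eq__(self, other) -> bool:
        if not isinstance(other, LinkSet):
            return NotImplemented
        return self._by_pair == other._by_pair

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)

    def by_concept(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, rid in self._by_pair:
            out.setdefault(cid, set()).add(rid)
        return out

    def concept_ids(self) -> set[str]:
        return {cid for cid, _ in self._by_pair}


@dataclass
class MappingReport:
    """Non-fatal skips encountered while importing a precomputed mapping."""

    n_links: int = 0
    unmatched_keys: list[str] = field(default_factory=list)
    unknown_concept_ids: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.unmatched_keys) + len(self.unknown_concept_ids)


@dataclass
class KnowledgeBase:
    """Ontology + association records + links + the gene universe.

    ``gene_universe`` is exactly the set of distinct gene symbols appearing
    in ``records``; it is the population the resampling null draws from.
    """

    ontology: Ontology
    records: dict[str, AssociationRecord]
    links: LinkSet
    gene_universe: set[str]

    def summary(self) -> dict[str, int]:
        return {
            "concepts": sum(1 for _ in self.ontology.active_concepts()),
            "records": len(self.records),
            "links": len(self.links),
            "genes": len(self.gene_universe),
            "concepts_with_links": len(self.links.concept_ids()),
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.ontology.concepts == other.ontology.concepts
            and self.records == other.records
            and self.links == other.links
            and self.gene_universe == other.gene_universe
        )


_REQUIRED_COLUMNS = {
    Source.GAD: ["record_id", "gene", "phenotype_text"],
    Source.GWASDB: ["record_id", "gene", "phenotype_text", "pvalue", "variant_id"],
}


def read_association_table(
    stream: str | TextIO, dialect: Source | str
) -> AssociationTable:
    """Read a tab-separated association table in the GAD or GWASDB dialect.

    The first line is a header; extra columns are ignored.  Rows with an
    empty gene or phenotype text are dropped and counted in
    ``AssociationTable.n_dropped``.  Missing required columns, duplicate
    record ids and unparsable p-values raise :class:`TableFormatError`.
    """
    dialect = Source(dialect)
    if dialect not in _REQUIRED_COLUMNS:
        raise ValueError(f"unsupported table dialect: {dialect}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(
            stream,
            sep="\t",
            dtype=str,
            keep_default_na=False,
            quoting=csv.QUOTE_NONE,
        )
    except pd.errors.EmptyDataError:
        raise TableFormatError("empty input: missing header line") from None

    for col in _REQUIRED_COLUMNS[dialect]:
        if col not in df.columns:
            raise TableFormatError(f"missing required column: {col}")

    records: list[AssociationRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        gene = getattr(row, "gene").strip().upper()
        text = getattr(row, "phenotype_text").strip()
        if not gene or not text:
            n_dropped += 1
            continue
        rid = getattr(row, "record_id").strip()
        if not rid:
            raise TableFormatError(f"row {i}: empty record_id")
        if rid in seen:
            raise TableFormatError(f"duplicate record_id: {rid}")
        seen.add(rid)
        pvalue = None
        variant = None
        if dialect is Source.GWASDB:
            raw_p = getattr(row, "pvalue").strip()
            if raw_p:
                try:
                    pvalue = float(raw_p)
                except ValueError:
                    raise TableFormatError(
                        f"row {i}: unparsable pvalue {raw_p!r}"
                    ) from None
                if not 0.0 < pvalue <= 1.0:
                    raise TableFormatError(
                        f"row {i}: pvalue {pvalue} outside (0, 1]"
                    )
            variant = getattr(row, "variant_id").strip() or None
        records.append(
            AssociationRecord(
                record_id=rid,
                gene=gene,
                phenotype_text=text,
                source=dialect,
                pvalue=pvalue,
                variant_id=variant,
            )
        )
    return AssociationTable(records=records, source=dialect, n_dropped=n_dropped)


def import_mapping(
    stream: str | TextIO, ontology: Ontology, table: AssociationTable
) -> tuple[LinkSet, MappingReport]:
    """Import a precomputed (phenotype_key, concept_id) mapping as links.

    A key matches records by exact case-folded equality with their phenotype
    text.  Unmatched keys and unknown (or obsolete) concept ids go into the
    returned :class:`MappingReport` instead of aborting the import.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    by_text: dict[str, list[str]] = {}
    for rec in table.records:
        by_text.setdefault(rec.phenotype_text.lower(), []).append(rec.record_id)

    links = LinkSet(source=table.source)
    report = MappingReport()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TableFormatError(
                f"mapping line {lineno}: expected 2 tab-separated fields, "
                f"got {len(parts)}"
            )
        key, cid = parts[0].strip().lower(), parts[1].strip()
        if not ontology.is_active(cid):
            report.unknown_concept_ids.append(cid)
            continue
        if key not in by_text:
            report.unmatched_keys.append(key)
            continue
        for rid in by_text[key]:
            links.add(cid, rid, "imported")
    report.n_links = len(links)
    return links, report


def build_knowledgebase(
    ontology: Ontology,
    tables: Iterable[AssociationTable],
    linksets: Iterable[LinkSet] = (),
) -> KnowledgeBase:
    """Merge tables and link sets into a validated :class:`KnowledgeBase`.

    Record ids colliding across sources are disambiguated by prefixing with
    the source name (``GAD:r1`` / ``GWASDB:r1``); links from a source-tagged
    LinkSet are remapped accordingly.  Links that cannot be resolved after
    the merge raise :class:`IntegrityError`.
    """
    tables = list(tables)
    linksets = list(linksets)

    id_tables: dict[str, list[Source]] = {}
    for t in tables:
        for rec in t.records:
            owners = id_tables.setdefault(rec.record_id, [])
            if t.source in owners:
                raise IntegrityError(
                    f"duplicate record_id {rec.record_id!r} within source "
                    f"{t.source.value}"
                )
            owners.append(t.source)

    remap: dict[Source, dict[str, str]] = {}
    records: dict[str, AssociationRecord] = {}
    for t in tables:
        for rec in t.records:
            rid = rec.record_id
            if len(id_tables[rid]) > 1:
                new_rid = f"{t.source.value}:{rid}"
                remap.setdefault(t.source, {})[rid] = new_rid
                rec = AssociationRecord(
                    new_rid, rec.gene, rec.phenotype_text, rec.source,
                    rec.pvalue, rec.variant_id,
                )
                rid = new_rid
            records[rid] = rec

    merged = LinkSet()
    for ls in linksets:
        table_map = remap.get(ls.source, {})
        for link in ls:
            rid = table_map.get(link.record_id, link.record_id)
            if rid not in records:
                raise IntegrityError(
                    f"link references unknown record {link.record_id!r}"
                )
            if not ontology.is_active(link.concept_id):
                raise IntegrityError(
                    f"link references unknown or obsolete concept "
                    f"{link.concept_id!r}"
                )
            merged.add(link.concept_id, rid, link.provenance)

    gene_universe = {rec.gene for rec in records.values()}
    return KnowledgeBase(
        ontology=ontology, records=records, links=merged,
        gene_universe=gene_universe,
    )


_SCHEMA = """
CREATE TABLE concept (id TEXT PRIMARY KEY, name TEXT, obsolete INT);
CREATE TABLE concept_parent (child TEXT, parent TEXT);
CREATE TABLE synonym (concept TEXT, label TEXT);
CREATE TABLE association (
    record_id TEXT PRIMARY KEY, gene TEXT, phenotype_text TEXT,
    source TEXT, pvalue REAL NULL, variant_id TEXT NULL
);
CREATE TABLE link (
    concept TEXT, record_id TEXT, provenance TEXT,
    UNIQUE(concept, record_id)
);
CREATE TABLE meta (key TEXT, value TEXT);
"""

_TABLES = ("concept", "concept_parent", "synonym", "association", "link", "meta")


def persist_kb(kb: KnowledgeBase, path: str | os.PathLike) -> None:
    """Write the knowledge base to ``path`` as a SQLite database."""
    path = os.fspath(path)
    if os.path.exists(path):
        os.remove(path)
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO concept VALUES (?, ?, ?)",
            [
                (c.id, c.name, int(c.obsolete))
                for c in kb.ontology.concepts.values()
            ],
        )
        con.executemany(
            "INSERT INTO concept_parent VALUES (?, ?)",
            [
                (c.id, p)
                for c in kb.ontology.concepts.values()
                for p in c.parent_ids
            ],
        )
        con.executemany(
            "INSERT INTO synonym VALUES (?, ?)",
            [
                (c.id, s)
                for c in kb.ontology.concepts.values()
                for s in c.synonyms
            ],
        )
        con.executemany(
            "INSERT INTO association VALUES (?, ?, ?, ?, ?, ?)",
            [
                (r.record_id, r.gene, r.phenotype_text, r.source.value,
                 r.pvalue, r.variant_id)
                for r in kb.records.values()
            ],
        )
        con.executemany(
            "INSERT INTO link VALUES (?, ?, ?)",
            [(l.concept_id, l.record_id, l.provenance) for l in kb.links],
        )
        con.execute("INSERT INTO meta VALUES ('schema_version', '1')")
        con.commit()
    finally:
        con.close()


def load_kb(path: str | os.PathLike) -> KnowledgeBase:
    """Load a knowledge base previously written by :func:`persist_kb`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StorageError(f"no such knowledge-base file: {path}")
    con = sqlite3.connect(path)
    try:
        have = {
            row[0]
            for row in con.execute(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            )
        }
        for t in _TABLES:
            if t not in have:
                raise StorageError(f"missing table: {t}")

        parents: dict[str, list[str]] = {}
        for child, parent in con.execute("SELECT child, parent FROM concept_parent"):
            parents.setdefault(child, []).append(parent)
        synonyms: dict[str, list[str]] = {}
        for cid, label in con.execute("SELECT concept, label FROM synonym"):
            synonyms.setdefault(cid, []).append(label)
        concepts = [
            Concept(
                id=cid,
                name=name,
                synonyms=synonyms.get(cid, []),
                parent_ids=parents.get(cid, []),
                obsolete=bool(obsolete),
            )
            for cid, name, obsolete in con.execute(
                "SELECT id, name, obsolete FROM concept"
            )
        ]
        ontology = Ontology(concepts)

        records: dict[str, AssociationRecord] = {}
        for rid, gene, text, source, pvalue, variant in con.execute(
            "SELECT record_id, gene, phenotype_text, source, pvalue, variant_id"
            " FROM association"
        ):
            try:
                src = Source(source)
            except ValueError:
                raise StorageError(f"unknown record source: {source!r}") from None
            records[rid] = AssociationRecord(rid, gene, text, src, pvalue, variant)

        links = LinkSet()
        for cid, rid, prov in con.execute(
            "SELECT concept, record_id, provenance FROM link"
        ):
            if rid not in records:
                raise IntegrityError(f"stored link references unknown record {rid!r}")
            if cid not in ontology:
                raise IntegrityError(f"stored link references unknown concept {cid!r}")
            links.add(cid, rid, prov)
    finally:
        con.close()

    gene_universe = {r.gene for r in records.values()}
    return KnowledgeBase(
        ontology=ontology, records=records, links=links, gene_universe=gene_universe
    )


def write_obo(ontology: Ontology) -> str:
    """Serialize an ontology back to OBO flat text (interpreted fields only)."""
    out = ["format-version: 1.2", ""]
    for c in ontology.concepts.values():
        out.append("[Term]")
        out.append(f"id: {c.id}")
        if c.name:
            out.append(f"name: {c.name}")
        for s in c.synonyms:
            escaped = s.replace('"', '\\"')
            out.append(f'synonym: "{escaped}" EXACT []')
        for p in c.parent_ids:
            parent = ontology.concepts.get(p)
            if parent is not None and parent.name:
                out.append(f"is_a: {p} ! {parent.name}")
            else:
                out.append(f"is_a: {p}")
        if c.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out) + "\n"
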