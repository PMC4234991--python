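"""Suffix-array substring matching between concept labels and phenotype texts.

A generalized suffix array is built over the case-folded free-text phenotype
descriptions; each ontology concept label is then located by binary search
(``O(|pattern| * log n)`` probes).  Matching is pure unanchored substring
containment, which is why very short labels ("EO", "ALS", "age", "CAD")
produce unspecific hits and are excluded by a stoplist and a minimum label
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .knowledgebase import AssociationTable, LinkSet
from .ontology import Ontology

__all__ = [
    "SENTINEL",
    "DEFAULT_STOPLIST",
    "SuffixIndex",
    "MatchConfig",
    "LabelOccurrence",
    "build_suffix_array",
    "find_occurrences",
    "map_labels",
]

#: Per-document terminator in the concatenated corpus; must not occur in input.
SENTINEL = "\x01"

#: Labels whose unanchored substring matches were found to be unspecific.
DEFAULT_STOPLIST = frozenset({"eo", "als", "age", "cad"})


def _suffix_array(text: str) -> np.ndarray:
    """Suffix array of ``text`` by prefix doubling (numpy lexsort)."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    # code points as initial ranks; utf-32-le yields one uint32 per character
    rank = np.frombuffer(text.encode("utf-32-le"), dtype=np.uint32).astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if int(rank[order[-1]]) == n - 1:
            return order.astype(np.intp)
        k *= 2


@dataclass
class SuffixIndex:
    """Generalized suffix array over a document collection.

    ``text`` is the case-folded concatenation of the documents, each followed
    by the sentinel terminator; ``doc_bounds`` are half-open ``[start, end)``
    offset pairs (the sentinel sits at ``end - 1``) partitioning the whole
    text in input order.
    """

    text: str
    sa: np.ndarray
    doc_bounds: list[tuple[int, int]]
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._starts = np.array([b[0] for b in self.doc_bounds], dtype=np.intp)

    @property
    def n_docs(self) -> int:
        return len(self.doc_bounds)

    def document(self, doc_index: int) -> str:
        start, end = self.doc_bounds[doc_index]
        return self.text[start : end - 1]


class LabelOccurrence(NamedTuple):
    """One occurrence of a concept label inside a document."""

    concept_id: str
    doc_index: int
    offset: int  # 0-based character offset within the document


@dataclass(frozen=True)
class MatchConfig:
    """Filtering and matching switches for label-to-text mapping.

    ``min_label_length`` and ``stoplist`` suppress short/ambiguous labels;
    ``use_synonyms`` extends matching beyond primary names; ``word_boundary``
    anchors matches at non-alphanumeric boundaries instead of pure substring.
    """

    min_label_length: int = 4
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    use_synonyms: bool = False
    word_boundary: bool = False

    def __post_init__(self):
        if self.min_label_length < 1:
            raise ValueError("min_label_length must be >= 1")
        object.__setattr__(
            self, "stoplist", frozenset(s.lower() for s in self.stoplist)
        )


def build_suffix_array(documents: Sequence[str]) -> SuffixIndex:
    """Case-fold ``documents`` and index every suffix of their concatenation."""
    folded = []
    for i, doc in enumerate(documents):
        if SENTINEL in doc:
            raise ValueError(f"document {i} contains the sentinel character")
        folded.append(doc.lower())
    bounds = []
    pos = 0
    for doc in folded:
        bounds.append((pos, pos + len(doc) + 1))
        pos += len(doc) + 1
    text = SENTINEL.join(folded) + SENTINEL if folded else ""
    return SuffixIndex(text=text, sa=_suffix_array(text), doc_bounds=bounds)


def find_occurrences(index: SuffixIndex, pattern: str) -> list[tuple[int, int]]:
    """Every ``(doc_index, offset)`` where ``pattern`` occurs as a substring.

    The pattern is case-folded before search; occurrences never span
    documents.  Results are sorted by ``(doc_index, offset)``.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    p = pattern.lower()
    m = len(p)
    text, sa = index.text, index.sa

    lo, hi = 0, len(sa)
    while lo < hi:  # first suffix with prefix >= p
        mid = (lo + hi) // 2
        if text[sa[mid] : sa[mid] + m] < p:
            lo = mid + 1
        else:
            hi = mid
    left = lo
    hi = len(sa)
    while lo < hi:  # first suffix with prefix > p
        mid = (lo + hi) // 2
        if text[sa[mid] : sa[mid] + m] <= p:
            lo = mid + 1
        else:
            hi = mid
    right = lo

    out = []
    for off in sorted(int(o) for o in sa[left:right]):
        doc = int(np.searchsorted(index._starts, off, side="right")) - 1
        start, end = index.doc_bounds[doc]
        if off + m <= end - 1:  # entirely within the document body
            out.append((doc, off - start))
    return out


def _word_bounded(doc: str, offset: int, length: int) -> bool:
    before_ok = offset == 0 or not doc[offset - 1].isalnum()
    after_ok = offset + length == len(doc) or not doc[offset + length].isalnum()
    return before_ok and after_ok


def _concept_labels(ontology: Ontology, config: MatchConfig):
    for concept in ontology.active_concepts():
        labels = [concept.name]
        if config.use_synonyms:
            labels.extend(concept.synonyms)
        for label in labels:
            folded = label.lower()
            if len(folded) < config.min_label_length or folded in config.stoplist:
                continue
            yield concept.id, folded


def find_label_occurrences(
    ontology: Ontology, index: SuffixIndex, config: MatchConfig = MatchConfig()
) -> list[LabelOccurrence]:
    """All occurrences of admissible concept labels in the indexed corpus."""
    occs = []
    for cid, label in _concept_labels(ontology, config):
        for doc, off in find_occurrences(index, label):
            if config.word_boundary and not _word_bounded(
                index.document(doc), off, len(label)
            ):
                continue
            occs.append(LabelOccurrence(cid, doc, off))
    return occs


def map_labels(
    ontology: Ontology,
    table: AssociationTable,
    config: MatchConfig = MatchConfig(),
) -> LinkSet:
    """Link concepts to association records by substring label occurrence.

    A suffix index is built over the distinct case-folded phenotype texts of
    ``table``; every admissible concept label (length >= min_label_length,
    not stoplisted) is searched, and one link is emitted per (concept,
    record) pair whose description contains the label.  The relation is
    many-to-many and deduplicated; provenance is marked ``"matched"``.
    """
    doc_of_text: dict[str, int] = {}
    docs: list[str] = []
    doc_records: list[list[str]] = []
    for rec in table.records:
        key = rec.phenotype_text.lower()
        if key not in doc_of_text:
            doc_of_text[key] = len(docs)
            docs.append(key)
            doc_records.append([])
        doc_records[doc_of_text[key]].append(rec.record_id)

    index = build_suffix_array(docs)
    links = LinkSet(source=table.source)
    for occ in find_label_occurrences(ontology, index, config):
        for rid in doc_records[occ.doc_index]:
            links.add(occ.concept_id, rid, "matched")
    return links
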