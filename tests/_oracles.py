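"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own data paths: substring search is a
naive per-document scan, reachability is a plain DFS over parent lists, and
label mapping is a quadratic containment loop.
"""

from __future__ import annotations

import numpy as np


def naive_occurrences(documents, pattern):
    """All (doc_index, offset) of case-folded substring hits, by direct scan."""
    p = pattern.lower()
    out = []
    for di, doc in enumerate(documents):
        d = doc.lower()
        start = 0
        while True:
            off = d.find(p, start)
            if off == -1:
                break
            out.append((di, off))
            start = off + 1
    return out


def brute_reachable(edges: dict[str, list[str]], start: str) -> set[str]:
    """Nodes reachable from ``start`` following ``edges``, excluding start."""
    seen: set[str] = set()
    stack = list(edges.get(start, ()))
    while stack:
        node = stack.pop()
        if node not in seen:
            seen.add(node)
            stack.extend(edges.get(node, ()))
    seen.discard(start)
    return seen


def invert(parents: dict[str, list[str]]) -> dict[str, list[str]]:
    children: dict[str, list[str]] = {k: [] for k in parents}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(child)
    return children


def random_dag(rng: np.random.Generator, n_nodes: int) -> dict[str, list[str]]:
    """Random DAG as id -> parent-id lists; node i may only point at j < i."""
    parents: dict[str, list[str]] = {}
    ids = [f"T:{i:07d}" for i in range(n_nodes)]
    for i, cid in enumerate(ids):
        if i == 0:
            parents[cid] = []
            continue
        k = int(rng.integers(1, min(3, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[cid] = [ids[int(j)] for j in sorted(chosen)]
    return parents


def dag_to_obo(parents: dict[str, list[str]]) -> str:
    chunks = []
    for cid, ps in parents.items():
        lines = ["[Term]", f"id: {cid}", f"name: term {cid}"]
        lines += [f"is_a: {p}" for p in ps]
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def quadratic_label_links(ontology, table, config):
    """(concept_id, record_id) pairs by a direct quadratic containment loop."""
    pairs = set()
    for concept in ontology.active_concepts():
        labels = [concept.name]
        if config.use_synonyms:
            labels.extend(concept.synonyms)
        for label in labels:
            folded = label.lower()
            if len(folded) < config.min_label_length:
                continue
            if folded in {s.lower() for s in config.stoplist}:
                continue
            for rec in table.records:
                if folded in rec.phenotype_text.lower():
                    pairs.add((concept.id, rec.record_id))
    return pairs
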