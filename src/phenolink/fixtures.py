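"""Synthetic OBO + association-table fixtures with known planted structure.

The generator emulates the shape of the real corpus — a phenotype-ontology
DAG, free-text phenotype descriptions, two association catalogues (one
linked by text matching, one by a precomputed phenotype-to-concept mapping)
— while guaranteeing ground truth by construction: chosen concepts are
forced to share exactly a chosen gene set after descendant closure, and
every other overlap is excluded by drawing private genes from disjoint
pools.

Default parameters reproduce the worked-example study conditions: four
leaf phenotype concepts (bulimia, schizophrenia, depression, psychosis)
whose descendant-closed gene sets hold 100 symbols each out of a
10,000-symbol universe and share exactly the four planted genes
COMT, HTR2A, SLC6A3 and SLC6A4.

Generated concept names use a fixed-length consonant-vowel syllable
alphabet and description filler uses a disjoint letter set, so no label can
occur in a description by accident; the ``hostile_labels`` mode deliberately
adds the short ambiguous labels ("EO", "ALS", "age", "CAD") to exercise the
stoplist.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import FixtureParamError
from .knowledgebase import Link, LinkSet, write_obo
from .ontology import Concept, Ontology

__all__ = [
    "Planting",
    "FixtureParams",
    "FixtureTruth",
    "Fixture",
    "generate_fixture",
    "write_fixture",
    "DEFAULT_NAMED_CONCEPTS",
    "DEFAULT_PLANTING",
]

_CONSONANTS = "bdfgklmnprst"
_VOWELS = "aeiou"
# filler vocabulary drawn from letters disjoint from the syllable alphabet
_FILLER_WORDS = (
    "zyq", "wch", "vjx", "hyz", "quw", "xcv", "jwy", "zqh",
    "wxv", "chy", "qjz", "vhw", "xyx", "zwj", "hqv", "ycx",
)
_HOSTILE_LABELS = ("EO", "ALS", "age", "CAD")

DEFAULT_NAMED_CONCEPTS = (
    ("HP:0000707", "neurological abnormality", None),
    ("HP:0100739", "bulimia", "HP:0000707"),
    ("HP:0100753", "schizophrenia", "HP:0000707"),
    ("HP:0000716", "depression", "HP:0000707"),
    ("HP:0000709", "psychosis", "HP:0000707"),
)


class Planting(NamedTuple):
    """Force ``concept_ids`` to share exactly ``genes`` after closure."""

    concept_ids: tuple[str, ...]
    genes: tuple[str, ...]


DEFAULT_PLANTING = (
    Planting(
        ("HP:0100739", "HP:0100753", "HP:0000716", "HP:0000709"),
        ("COMT", "HTR2A", "SLC6A3", "SLC6A4"),
    ),
)

_ROOT_ID = "HP:0000001"


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic corpus; defaults are the worked-example shape."""

    n_concepts: int = 30
    max_children: int = 6
    n_phenotype_texts: int = 40
    n_records_per_source: int = 5000
    universe: int | tuple[str, ...] = 10_000
    planted: tuple[Planting, ...] = DEFAULT_PLANTING
    planted_set_size: int = 100
    named_concepts: tuple[tuple[str, str, str | None], ...] = DEFAULT_NAMED_CONCEPTS
    hostile_labels: bool = False
    seed: int = 0


@dataclass
class FixtureTruth:
    """Exact ground truth the generator guarantees by construction."""

    planted: tuple[Planting, ...]
    expected_links: LinkSet
    per_concept_expected_genes: dict[str, set[str]]
    hostile_concept_ids: tuple[str, ...] = ()


class Fixture(NamedTuple):
    obo_text: str
    gad_tsv: str
    gwasdb_tsv: str
    mapping_tsv: str
    truth: FixtureTruth


def _syllable_name(rng: np.random.Generator, n_syllables: int = 4) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _filler(rng: np.random.Generator, n_words: int) -> list[str]:
    return [_FILLER_WORDS[rng.integers(len(_FILLER_WORDS))] for _ in range(n_words)]


def _build_universe(params: FixtureParams) -> list[str]:
    planted_genes: list[str] = []
    for p in params.planted:
        for g in p.genes:
            if g not in planted_genes:
                planted_genes.append(g)
    if isinstance(params.universe, int):
        if params.universe < len(planted_genes):
            raise FixtureParamError(
                "universe size smaller than the number of planted genes"
            )
        pad = [
            f"G{i:05d}" for i in range(1, params.universe - len(planted_genes) + 1)
        ]
        return planted_genes + pad
    universe = list(params.universe)
    missing = [g for g in planted_genes if g not in universe]
    if missing:
        raise FixtureParamError(f"planted genes not in universe: {missing}")
    if len(set(universe)) != len(universe):
        raise FixtureParamError("universe contains duplicate gene symbols")
    return universe


def _build_ontology(
    params: FixtureParams, rng: np.random.Generator
) -> tuple[list[Concept], dict[str, list[str]], tuple[str, ...]]:
    """Returns (concepts, children map, hostile ids)."""
    concepts: list[Concept] = [Concept(_ROOT_ID, "phenotypic abnormality")]
    ids = {_ROOT_ID}
    for cid, name, parent in params.named_concepts:
        parent = parent or _ROOT_ID
        if parent not in ids:
            raise FixtureParamError(f"named concept {cid} has unknown parent {parent}")
        if cid in ids:
            raise FixtureParamError(f"duplicate named concept id {cid}")
        concepts.append(Concept(cid, name, parent_ids=[parent]))
        ids.add(cid)

    planted_ids = {cid for p in params.planted for cid in p.concept_ids}
    for p in params.planted:
        for cid in p.concept_ids:
            if cid not in ids:
                raise FixtureParamError(f"planted concept {cid} is not generated")

    existing_names = {c.name.lower() for c in concepts}
    n_extra = params.n_concepts - len(concepts)
    if n_extra < 0:
        raise FixtureParamError(
            f"n_concepts={params.n_concepts} smaller than root + named concepts"
        )
    child_count: dict[str, int] = {c.id: 0 for c in concepts}
    for c in concepts[1:]:
        for p in c.parent_ids:
            child_count[p] = child_count.get(p, 0) + 1

    for i in range(n_extra):
        cid = f"HP:09{i:05d}"
        while True:
            name = _syllable_name(rng)
            clash = name in existing_names or any(
                name in other or other in name for other in existing_names
            )
            if not clash:
                break
        existing_names.add(name)
        # parents among earlier concepts; planted concepts stay leaves
        candidates = [
            c.id
            for c in concepts
            if c.id not in planted_ids
            and (child_count.get(c.id, 0) < params.max_children or c.id == _ROOT_ID)
        ]
        n_par = 2 if (len(candidates) >= 2 and rng.random() < 0.3) else 1
        chosen = rng.choice(len(candidates), size=n_par, replace=False)
        parent_ids = sorted(candidates[int(j)] for j in chosen)
        concepts.append(Concept(cid, name, parent_ids=parent_ids))
        for p in parent_ids:
            child_count[p] = child_count.get(p, 0) + 1
        child_count[cid] = 0

    hostile_ids: tuple[str, ...] = ()
    if params.hostile_labels:
        hostile = []
        for j, label in enumerate(_HOSTILE_LABELS):
            hid = f"HP:08{j:05d}"
            concepts.append(Concept(hid, label, parent_ids=[_ROOT_ID]))
            hostile.append(hid)
        hostile_ids = tuple(hostile)

    # user-supplied named labels must not nest inside one another
    named_labels = [name.lower() for _, name, _ in params.named_concepts]
    for a in named_labels:
        for b in named_labels:
            if a != b and a in b:
                raise FixtureParamError(
                    f"named concept label {a!r} is a substring of {b!r}"
                )

    children: dict[str, list[str]] = {c.id: [] for c in concepts}
    for c in concepts:
        for p in c.parent_ids:
            children[p].append(c.id)
    return concepts, children, hostile_ids


def _closure_descendants(children: dict[str, list[str]], cid: str) -> set[str]:
    # local reachability, independent of the ontology module
    out: set[str] = set()
    stack = list(children.get(cid, ()))
    while stack:
        x = stack.pop()
        if x not in out:
            out.add(x)
            stack.extend(children.get(x, ()))
    return out


def generate_fixture(params: FixtureParams = FixtureParams()) -> Fixture:
    """Generate (obo_text, gad_tsv, gwasdb_tsv, mapping_tsv, truth).

    Deterministic given ``params.seed``: the same parameters always yield
    byte-identical files and an identical truth record.
    """
    rng = np.random.default_rng(params.seed)
    universe = _build_universe(params)
    concepts, children, hostile_ids = _build_ontology(params, rng)
    ontology = Ontology(concepts)  # validates acyclicity
    by_id = {c.id: c for c in concepts}
    planted_ids = [cid for p in params.planted for cid in p.concept_ids]
    planted_id_set = set(planted_ids)
    named_id_set = {cid for cid, _, _ in params.named_concepts}

    if params.n_records_per_source == 0:
        if params.planted:
            raise FixtureParamError(
                "plantings require n_records_per_source > 0"
            )
        empty_truth = FixtureTruth(
            planted=(), expected_links=LinkSet(),
            per_concept_expected_genes={c.id: set() for c in concepts},
            hostile_concept_ids=hostile_ids,
        )
        return Fixture(
            obo_text=write_obo(ontology),
            gad_tsv="record_id\tgene\tphenotype_text\n",
            gwasdb_tsv="record_id\tgene\tphenotype_text\tpvalue\tvariant_id\n",
            mapping_tsv="",
            truth=empty_truth,
        )

    # --- gene bookkeeping: planted genes first, then a shuffled free pool
    planted_genes = {g for p in params.planted for g in p.genes}
    free_pool = [g for g in universe if g not in planted_genes]
    rng.shuffle(free_pool)
    free_iter = iter(free_pool)

    gene_sets: dict[str, list[str]] = {}
    for p in params.planted:
        n_private = params.planted_set_size - len(p.genes)
        if n_private < 0:
            raise FixtureParamError(
                "planted_set_size smaller than the planted gene list"
            )
        for cid in p.concept_ids:
            if cid in gene_sets:
                raise FixtureParamError(
                    f"concept {cid} appears in more than one planting"
                )
            private = []
            for _ in range(n_private):
                try:
                    private.append(next(free_iter))
                except StopIteration:
                    raise FixtureParamError(
                        "universe too small for the requested plantings"
                    ) from None
            gene_sets[cid] = list(p.genes) + private

    # --- descriptions
    background_ids = [
        c.id
        for c in concepts
        if c.id not in planted_id_set
        and c.id not in named_id_set
        and c.id != _ROOT_ID
        and c.id not in hostile_ids
    ]
    canonical_desc = {
        cid: " ".join(_filler(rng, 1) + [by_id[cid].name] + _filler(rng, 1))
        for cid in planted_ids
    }
    background_texts: list[tuple[str, str | None]] = []  # (text, linked concept)
    for i in range(params.n_phenotype_texts):
        if background_ids and rng.random() < 0.7:
            cid = background_ids[int(rng.integers(len(background_ids)))]
            text = " ".join(_filler(rng, 1) + [by_id[cid].name] + _filler(rng, 1))
            background_texts.append((text, cid))
        else:
            background_texts.append((" ".join(_filler(rng, 3)) + f" q{i:03d}", None))
    if not background_texts:
        background_texts.append((" ".join(_filler(rng, 3)) + " q000", None))
    if params.hostile_labels:
        for j, hid in enumerate(hostile_ids):
            label = by_id[hid].name.lower()
            # label embedded inside a longer word: unspecific substring hit
            background_texts.append(
                (f"zw{label}yx " + " ".join(_filler(rng, 2)), None)
            )
    gwas_key = {
        cid: f"q{idx:04d} " + " ".join(_filler(rng, 2))
        for idx, cid in enumerate(planted_ids)
    }
    gwas_bg_keys: list[tuple[str, str | None]] = []
    for idx, cid in enumerate(background_ids[: max(1, len(background_ids) // 2)]):
        gwas_bg_keys.append((f"w{idx:04d} " + " ".join(_filler(rng, 2)), cid))

    # --- records
    gad_rows: list[tuple[str, str, str]] = []
    gwas_rows: list[tuple[str, str, str, str, str]] = []
    mapping_rows: list[tuple[str, str]] = []
    expected = LinkSet()
    direct_genes: dict[str, set[str]] = {c.id: set() for c in concepts}

    def add_gad(gene: str, text: str, cid: str | None) -> str:
        rid = f"gad{len(gad_rows) + 1:06d}"
        gad_rows.append((rid, gene, text))
        if cid is not None:
            expected.add(cid, rid, "matched")
            direct_genes[cid].add(gene)
        return rid

    def add_gwas(gene: str, text: str, cid: str | None) -> str:
        rid = f"gw{len(gwas_rows) + 1:06d}"
        pv = f"{10 ** (-float(rng.uniform(3, 8))):.3e}"
        variant = f"rs{int(rng.integers(10_000, 10_000_000))}"
        gwas_rows.append((rid, gene, text, pv, variant))
        if cid is not None:
            expected.add(cid, rid, "imported")
            direct_genes[cid].add(gene)
        return rid

    for cid in planted_ids:
        mapping_rows.append((gwas_key[cid], cid))
    for key, cid in gwas_bg_keys:
        mapping_rows.append((key, cid))

    toggle = 0
    for cid in planted_ids:
        for gene in gene_sets[cid]:
            if toggle % 2 == 0:
                add_gad(gene, canonical_desc[cid], cid)
            else:
                add_gwas(gene, gwas_key[cid], cid)
            toggle += 1

    # background: cover the remaining universe, then top up to the per-source
    # minimum; descriptions may carry a background concept name (text match)
    # or a mapped key (import), or be pure noise
    remaining = list(free_iter)
    n_bg_min = max(
        len(remaining),
        2 * params.n_records_per_source - len(gad_rows) - len(gwas_rows),
    )
    reuse_pool = universe
    for j in range(n_bg_min):
        gene = remaining[j] if j < len(remaining) else (
            reuse_pool[int(rng.integers(len(reuse_pool)))]
        )
        if j % 2 == 0:
            text, cid = background_texts[int(rng.integers(len(background_texts)))]
            add_gad(gene, text, cid)
        else:
            if gwas_bg_keys and rng.random() < 0.5:
                key, cid = gwas_bg_keys[int(rng.integers(len(gwas_bg_keys)))]
                add_gwas(gene, key, cid)
            else:
                text, _ = background_texts[int(rng.integers(len(background_texts)))]
                add_gwas(gene, text, None)

    # GWAS background rows whose description holds a concept name would also
    # be matched if text-matching ran over that table; the truth only claims
    # the import route for them, hence cid=None above.

    # --- truth closure over the generator's own DAG bookkeeping
    per_concept: dict[str, set[str]] = {}
    for c in concepts:
        ids = {c.id} | _closure_descendants(children, c.id)
        per_concept[c.id] = set().union(*(direct_genes[x] for x in ids))

    truth = FixtureTruth(
        planted=params.planted,
        expected_links=expected,
        per_concept_expected_genes=per_concept,
        hostile_concept_ids=hostile_ids,
    )

    gad_tsv = "record_id\tgene\tphenotype_text\n" + "".join(
        f"{r}\t{g}\t{t}\n" for r, g, t in gad_rows
    )
    gwasdb_tsv = (
        "record_id\tgene\tphenotype_text\tpvalue\tvariant_id\n"
        + "".join(
            f"{r}\t{g}\t{t}\t{p}\t{v}\n" for r, g, t, p, v in gwas_rows
        )
    )
    mapping_tsv = "".join(f"{k}\t{c}\n" for k, c in mapping_rows)
    return Fixture(
        obo_text=write_obo(ontology),
        gad_tsv=gad_tsv,
        gwasdb_tsv=gwasdb_tsv,
        mapping_tsv=mapping_tsv,
        truth=truth,
    )


def write_fixture(
    params: FixtureParams, directory: str | os.PathLike
) -> dict[str, str]:
    """Write a generated fixture into ``directory``; returns name -> path."""
    fixture = generate_fixture(params)
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, content in (
        ("ontology.obo", fixture.obo_text),
        ("gad.tsv", fixture.gad_tsv),
        ("gwasdb.tsv", fixture.gwasdb_tsv),
        ("mapping.tsv", fixture.mapping_tsv),
    ):
        path = os.path.join(os.fspath(directory), name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(content)
        paths[name] = path
    return paths
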