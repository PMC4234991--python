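"""Gene-set intersection across phenotype concepts and its resampling null.

A concept's gene set is descendant-closed: it unions the genes of every
association linked to the concept or to any concept below it in the DAG.
The observed overlap of several concepts' gene sets is assessed against a
null in which each concept's set is replaced by a uniform random draw of the
same size (without replacement) from the knowledge base's gene universe.
The empirical p-value repeats this resampling until a draw matches or beats
the observed overlap, up to a trial cap (1,000 by default); zero successes
at the cap are reported as the bound p < 1/cap.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import UnsupportedSizeError
from .knowledgebase import KnowledgeBase
from .ontology import descendants

__all__ = [
    "IntersectionResult",
    "PValueParams",
    "PValueResult",
    "concept_gene_set",
    "intersect_genes",
    "empirical_pvalue",
    "exact_overlap_null",
]


@dataclass
class IntersectionResult:
    """Observed gene overlap of a concept selection.

    ``per_concept_genes`` holds each concept's descendant-closed gene set;
    ``common_genes`` is their intersection and ``k_observed`` its size.
    """

    concept_ids: list[str]
    per_concept_genes: dict[str, set[str]]
    common_genes: set[str]
    k_observed: int


@dataclass(frozen=True)
class PValueParams:
    """Resampling parameters.

    ``max_trials`` caps the number of random redraws (default 1,000);
    ``early_stop`` stops at the first null draw matching the observed
    overlap, reporting 1/trials; with ``early_stop`` off all trials run and
    the estimate is (successes + 1) / (max_trials + 1).  ``sampling_unit``
    chooses whether per-concept null draws match the size of the distinct
    gene set (default) or the number of linked association rows.
    """

    max_trials: int = 1000
    seed: int = 0
    early_stop: bool = True
    sampling_unit: Literal["distinct_genes", "association_rows"] = "distinct_genes"

    def __post_init__(self):
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.sampling_unit not in ("distinct_genes", "association_rows"):
            raise ValueError(f"unknown sampling_unit: {self.sampling_unit}")


@dataclass
class PValueResult:
    """Outcome of the resampling test.

    When no success occurs within the trial cap, ``is_bound`` is set and
    ``p_estimate`` is the upper bound 1/max_trials (render as "p < 1/N").
    """

    k_observed: int
    trials_run: int
    successes: int
    p_estimate: float
    is_bound: bool
    seed: int


def concept_gene_set(kb: KnowledgeBase, concept_id: str) -> set[str]:
    """Genes of all records linked to ``concept_id`` or any of its descendants."""
    ids = {concept_id} | descendants(kb.ontology, concept_id)
    by_concept = kb.links.by_concept()
    genes: set[str] = set()
    for cid in ids:
        for rid in by_concept.get(cid, ()):
            genes.add(kb.records[rid].gene)
    return genes


def _closure_record_ids(kb: KnowledgeBase, concept_id: str) -> set[str]:
    ids = {concept_id} | descendants(kb.ontology, concept_id)
    by_concept = kb.links.by_concept()
    rids: set[str] = set()
    for cid in ids:
        rids |= by_concept.get(cid, set())
    return rids


def _check_selection(concept_ids: Sequence[str]) -> list[str]:
    ids = list(concept_ids)
    if not ids:
        raise ValueError("at least one concept id is required")
    if len(set(ids)) != len(ids):
        raise ValueError("concept ids must be distinct")
    return ids


def intersect_genes(
    kb: KnowledgeBase, concept_ids: Sequence[str]
) -> IntersectionResult:
    """Descendant-closed gene sets of each concept and their intersection."""
    ids = _check_selection(concept_ids)
    per = {cid: concept_gene_set(kb, cid) for cid in ids}
    common = set.intersection(*per.values())
    return IntersectionResult(
        concept_ids=ids,
        per_concept_genes=per,
        common_genes=common,
        k_observed=len(common),
    )


def empirical_pvalue(
    kb: KnowledgeBase,
    concept_ids: Sequence[str],
    params: PValueParams = PValueParams(),
) -> PValueResult:
    """Resampling p-value for the observed multi-concept gene overlap.

    Each trial independently draws, for every selected concept, a uniform
    random subset of the gene universe of the same size as that concept's
    observed set (without replacement within a concept, independent across
    concepts and trials); the trial succeeds when the sampled sets share at
    least ``k_observed`` genes.  Fully reproducible given ``params.seed``.
    """
    inter = intersect_genes(kb, concept_ids)
    k = inter.k_observed
    universe = sorted(kb.gene_universe)

    if params.sampling_unit == "distinct_genes":
        sizes = [len(inter.per_concept_genes[cid]) for cid in inter.concept_ids]
        pool_size = len(universe)
        gene_code = None
    else:
        all_rids = sorted(kb.records)
        rid_index = {rid: i for i, rid in enumerate(all_rids)}
        gene_of = sorted({kb.records[rid].gene for rid in all_rids})
        gene_idx = {g: i for i, g in enumerate(gene_of)}
        gene_code = np.array(
            [gene_idx[kb.records[rid].gene] for rid in all_rids], dtype=np.intp
        )
        sizes = [
            len(_closure_record_ids(kb, cid)) for cid in inter.concept_ids
        ]
        pool_size = len(all_rids)
        del rid_index

    for cid, n in zip(inter.concept_ids, sizes):
        if n > pool_size:
            raise ValueError(
                f"sample size {n} for {cid} exceeds the sampling pool "
                f"({pool_size})"
            )

    rng = np.random.default_rng(params.seed)

    def one_trial() -> bool:
        sampled: list[set[int]] = []
        for n in sizes:
            idx = rng.choice(pool_size, size=n, replace=False)
            if gene_code is None:
                sampled.append(set(idx.tolist()))
            else:
                sampled.append(set(gene_code[idx].tolist()))
        return len(set.intersection(*sampled)) >= k if sampled else True

    if params.early_stop:
        for t in range(1, params.max_trials + 1):
            if one_trial():
                return PValueResult(
                    k_observed=k, trials_run=t, successes=1,
                    p_estimate=1.0 / t, is_bound=False, seed=params.seed,
                )
        return PValueResult(
            k_observed=k, trials_run=params.max_trials, successes=0,
            p_estimate=1.0 / params.max_trials, is_bound=True, seed=params.seed,
        )

    successes = sum(one_trial() for _ in range(params.max_trials))
    return PValueResult(
        k_observed=k,
        trials_run=params.max_trials,
        successes=successes,
        p_estimate=(successes + 1) / (params.max_trials + 1),
        is_bound=False,
        seed=params.seed,
    )


def exact_overlap_null(
    set_sizes: Sequence[int], universe_size: int, k: int
) -> float:
    """Exact P(common intersection >= k) for independent uniform subsets.

    For two sets the overlap is hypergeometric and the tail is evaluated in
    closed form.  For more sets the probability is obtained by exhaustive
    enumeration over all subset combinations (as bitmask counting), which is
    deliberately restricted to ``universe_size <= 12``.
    """
    sizes = list(set_sizes)
    if not sizes:
        raise ValueError("at least one set size is required")
    if k < 0:
        raise ValueError("k must be >= 0")
    if universe_size < 0 or any(n < 0 or n > universe_size for n in sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    if k == 0:
        return 1.0
    if len(sizes) == 1:
        return 1.0 if sizes[0] >= k else 0.0
    if len(sizes) == 2:
        # |S1 & S2| ~ Hypergeom(N=U, K=n1, n=n2)
        return float(hypergeom.sf(k - 1, universe_size, sizes[0], sizes[1]))
    if universe_size > 12:
        raise UnsupportedSizeError(
            "exact enumeration supports universe_size <= 12 for more than "
            "two sets"
        )

    universe = range(universe_size)
    dist: dict[int, int] = defaultdict(int)
    for combo in combinations(universe, sizes[0]):
        mask = 0
        for i in combo:
            mask |= 1 << i
        dist[mask] += 1
    for n in sizes[1:]:
        masks = []
        for combo in combinations(universe, n):
            mask = 0
            for i in combo:
                mask |= 1 << i
            masks.append(mask)
        nxt: dict[int, int] = defaultdict(int)
        for cur, count in dist.items():
            for m in masks:
                nxt[cur & m] += count
        dist = nxt

    total = math.prod(math.comb(universe_size, n) for n in sizes)
    hits = sum(c for mask, c in dist.items() if mask.bit_count() >= k)
    return hits / total
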