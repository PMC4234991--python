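# phenolink

Navigate a human-phenotype ontology that also carries genetic-association
data, and test whether phenotypes of interest share more genes than chance
would allow.

Genome-wide association studies report many gene–phenotype associations,
but for complex diseases individually robust associations are elusive. One
way to lend weight to an unconfirmed association is *in silico*
replication: if the same genes are associated with several distinct but
ontologically related phenotypes, the association is less likely to be
spurious. `phenolink` supports this analysis end to end:

1. **Knowledge base.** An ontology in OBO format (a DAG of concepts such as
   HPO terms, connected by `is_a` edges) is combined with genetic
   association tables. Free-text phenotype descriptions (GAD-style tables)
   are linked to concepts by exact case-folded substring matching over a
   generalized **suffix array**; tables that ship with a precomputed
   phenotype→concept mapping (GWASdb-style) are linked by importing it.
   Links are many-to-many and stored, with the ontology and records, in a
   single SQLite file. Short ambiguous labels ("EO", "ALS", "age", "CAD")
   are excluded from text matching by a stoplist and a minimum label
   length (4 characters by default).
2. **Descendant-closed gene sets.** The gene set of a concept *c* is
   `G(c) = { gene(r) : r linked to c or to any descendant of c }`, so a
   parent phenotype inherits the associations of everything below it.
3. **Overlap statistic.** For selected concepts `c_1..c_m` the observed
   overlap is `k = |G(c_1) ∩ … ∩ G(c_m)|`. Its empirical p-value is
   estimated by resampling: each trial draws, for every concept, a uniform
   random subset of the knowledge base's gene universe of size `|G(c_i)|`
   (without replacement), and succeeds when the sampled sets share at
   least `k` genes. Sampling repeats until the first success or a trial
   cap `N` (default 1,000); zero successes are reported as the bound
   `p < 1/N`. An exact small-scale null (`exact_overlap_null`, via the
   hypergeometric tail for two sets and exhaustive enumeration for more)
   serves as the calibration oracle.

A synthetic-fixture generator produces OBO + TSV corpora with planted gene
overlaps and an exact ground-truth record, so the whole pipeline is
testable without any external download.

## Worked example

Generate the default synthetic corpus — four leaf phenotype concepts
(bulimia, schizophrenia, depression, psychosis) whose descendant-closed
gene sets contain 100 symbols each, drawn from a 10,000-symbol universe and
sharing exactly the four planted genes — then build and query the knowledge
base:

```sh
phenolink fixture --out fx --seed 11
phenolink build --obo fx/ontology.obo --gad fx/gad.tsv \
    --gwasdb fx/gwasdb.tsv --mapping fx/mapping.tsv --out kb.sqlite
```

    concepts	30
    records	10012
    links	6377
    genes	10000
    concepts_with_links	26

The build report counts ontology concepts, association records, distinct
(concept, record) links, distinct gene symbols and concepts holding at
least one link. Intersect the four phenotypes:

```sh
phenolink intersect kb.sqlite HP:0100739 HP:0100753 HP:0000716 HP:0000709
```

    genes	HP:0100739	100
    genes	HP:0100753	100
    genes	HP:0000716	100
    genes	HP:0000709	100
    common	COMT,HTR2A,SLC6A3,SLC6A4
    k	4

Each phenotype's closed gene set has 100 genes; exactly the four planted
genes are common to all four (`k = 4`). Ask how surprising that is:

```sh
phenolink pvalue kb.sqlite HP:0100739 HP:0100753 HP:0000716 HP:0000709 \
    --max-trials 1000 --seed 42
```

    k_observed	4
    trials_run	1000
    successes	0
    p < 0.001

No random redraw of four 100-gene sets from the 10,000-gene universe
reached a four-gene common overlap in 1,000 trials, so the empirical
p-value is bounded above by 1/1000. `phenolink search` and
`phenolink show` support substring concept search and parent/child
navigation; the same operations are available as library functions
(`phenolink.parse_obo`, `map_labels`, `intersect_genes`,
`empirical_pvalue`, …).

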