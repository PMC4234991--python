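# Methods

## Data model

The knowledge base joins three ingredients:

* **Ontology** — a DAG of phenotype concepts parsed from OBO flat text.
  Only `[Term]` stanzas and the keys `id`, `name`, `synonym`, `is_a`,
  `is_obsolete` are interpreted; `is_a` targets are stripped of trailing
  `! comment` text. Duplicate ids, dangling `is_a` targets and cycles are
  hard errors: every downstream closure computation assumes a valid DAG,
  so a cyclic input is rejected outright (with one offending path in the
  error) rather than warned about. Obsolete terms are recorded but take no
  part in navigation, search or linking, matching common consumer
  practice for HPO releases. Multiple parentage is fully supported;
  closures deduplicate nodes reached along several paths.
* **Association records** — rows of tab-separated tables pairing a gene
  symbol with a free-text phenotype description, optionally with a source
  p-value and variant id. Two dialects are read: a minimal GAD-style
  table (`record_id`, `gene`, `phenotype_text`) and a GWASdb-style table
  that adds `pvalue` and `variant_id`. The GAD-style dialect is a
  documented column map rather than the historical dump format (the
  original catalogue is retired); a real dump adapts with a header
  rename. Gene symbols are uppercased for identity and no alias
  resolution is attempted. Rows lacking a gene or description are dropped
  and counted.
* **Links** — many-to-many (concept, record) pairs with provenance
  `matched` (text index) or `imported` (precomputed mapping). Duplicate
  pairs collapse to one; link counts therefore mean distinct pairs.
  Record-id collisions across sources are resolved by prefixing with the
  source name; link sets carry a source tag so their ids can be remapped
  consistently, and an ambiguous reference is an integrity error.

Persistence is a plain SQLite schema (`concept`, `concept_parent`,
`synonym`, `association`, `link`, `meta`); `load(persist(kb))` is the
identity on every interpreted field, which the suite asserts on a
500-concept corpus.

## Text matching

Concept labels are linked to descriptions by exact case-folded substring
occurrence. A generalized suffix array is built over the distinct folded
descriptions (prefix-doubling construction on the concatenated text, one
control-character sentinel per document); each label is located by binary
search in `O(|label| · log n)` probes. Indexing the descriptions and
querying each label yields the identical link relation to the opposite
orientation (indexing the labels) while keeping fewer, longer documents;
a quadratic containment oracle in the tests guarantees the equivalence.

Matching is deliberately unanchored — no stemming, no punctuation
handling, simple Unicode lowercasing — because that is what the link
relation is defined over. Unanchored matching makes very short labels
unspecific, so two explicit, auditable filters apply: a minimum label
length (default 4 characters; the known-problematic labels are 2–3
characters, and 4 is this package's choice of threshold) and a stoplist
(default `{"eo", "als", "age", "cad"}`). A `word_boundary` switch anchors
matches at non-alphanumeric boundaries, and `use_synonyms` extends
matching from primary names to synonyms; both default to off, so the
default behaviour is names-only pure substring matching.

## Gene-set overlap and its null

`concept_gene_set(kb, c)` is descendant-closed: the union of genes of all
records linked to `c` or to any concept below it. It is monotone under
the ancestor relation by construction. `intersect_genes` intersects the
closed sets of a selection and reports the overlap size `k`.

`empirical_pvalue` resamples the null in which each concept's set is
replaced by a uniform draw of the same size from the gene universe —
without replacement within a concept, independent across concepts and
trials. The universe is the set of distinct gene symbols present in the
knowledge base, not an external gene catalogue: the overlap is measured
among mapped genes, so the null is drawn from them too.

Two estimators are offered:

* **early stopping** (default, trial cap `N = 1000`): stop at the first
  trial whose sampled sets share at least `k` genes and report `1/t`;
  after `N` failures report the upper bound `p < 1/N` (`is_bound` set).
  This mirrors repeat-until-found sampling with a cap.
* **fixed-N** (`early_stop=False`): run all `N` trials and report the
  positively biased-safe estimate `(s + 1) / (N + 1)`. This mode is the
  one used for calibration tests, since its success frequency `s/N` is an
  unbiased binomial estimate of the null tail.

The sampling unit defaults to `distinct_genes` — each null draw matches
the size of the concept's distinct gene set, the quantity the overlap is
defined over. An `association_rows` mode instead draws as many records as
the concept's closure holds and reduces them to genes, for sensitivity
analysis when one gene carries many records.

With `k = 0` the first trial succeeds trivially (any intersection has
size ≥ 0) and the estimate is 1. All draws come from one seeded
`numpy.random.default_rng` generator, so identical parameters give
bitwise-identical results.

`exact_overlap_null(sizes, U, k)` is the test oracle for the sampler:
for two sets the overlap is `Hypergeom(N=U, K=n1, n=n2)` and the tail is
evaluated in closed form; for more sets the exact probability is obtained
by exhaustive enumeration over all subset combinations, implemented as
bitmask counting and deliberately restricted to `U ≤ 12` (beyond that it
raises rather than approximate). The suite checks the sampler against the
closed form at `U = 1000`, sizes 50/50, `k = 5` over 20,000 trials and
against enumeration at `U = 12` for three sets, both within three
Monte-Carlo standard errors; the enumeration itself is pinned to an
independently hand-derived value (49/225 for three 2-subsets of a
6-element universe overlapping in at least one element).

## Synthetic fixtures

The generator emulates the structure of the real corpus — an ontology
DAG, description texts embedding concept names, two association
catalogues linked by different routes — with exact ground truth by
construction. Default parameters are the worked-example conditions: four
leaf phenotype concepts under a common "neurological abnormality" parent,
each with a descendant-closed gene set of 100 symbols from a
10,000-symbol universe, sharing exactly the four planted genes COMT,
HTR2A, SLC6A3 and SLC6A4; a 30-concept ontology and at least 5,000
records per source (the generator tops background records up so that
every universe symbol occurs in at least one record, making the knowledge
base's gene universe exactly the requested 10,000 symbols).

Exactness of the planted overlap is guaranteed by drawing each planted
concept's private genes from disjoint slices of the universe and keeping
planted concepts as leaves; accidental label hits are excluded by
construction — generated names are fixed-length strings over a
consonant–vowel syllable alphabet (distinct fixed-length names cannot
nest) and description filler uses a disjoint letter set. A
`hostile_labels` mode deliberately adds the short ambiguous labels to
exercise the stoplist. What the fixtures do **not** emulate: realistic
HPO topology beyond random-DAG shape, GWAS effect sizes, linkage
structure, synonym-rich vocabularies or noisy clinical prose — so passing
tests certify the algorithms and their calibration, not recall on real
free text.

## Problem sizes and numerical choices

The suite exercises suffix arrays on 200 random corpora (≤ 5 kB, 50
patterns each) against a naive scan, label mapping on 100 random corpora
against the quadratic oracle, closures on 100 random DAGs (≤ 200 nodes)
against brute-force reachability, and the calibrations above; these sizes
give tight Monte-Carlo error at interactive runtimes. Suffix-array
construction uses prefix doubling (`O(n log² n)`); any correct
construction would do, as only the sortedness invariant is relied upon.
Search ordering breaks ties by (name length, id) so the most specific
concept leads deterministically. Seeds appearing in tests and the
acceptance script are arbitrary fixed integers; the acceptance script
derives both the fixture seed and the resampling seed from its `--seed`
argument.

## Known limitations

* Analytic p-values for more than two sets at realistic sizes are out of
  scope; the enumeration oracle is intentionally small-scale.
* Single-selection testing only: no multiple-testing correction across
  many concept selections.
* No fuzzy or vocabulary-normalized concept recognition; matching is
  exact substring after lowercasing.
* Gene identity is the uppercased symbol; aliases and identifier drift
  between catalogues are not reconciled.
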