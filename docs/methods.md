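# Methods

## Problem setting

A tabular dataset is a header row plus columns of string cells. A generic
tabular-to-RDF converter turns each row into an entity and mints one
predicate per column from the header text; those predicates exist in no
public ontology ("undefined terminology"). Semantic enhancement replaces
them with terms from public biomedical ontologies, guided by whether the
dataset carries a target concept (gene). The package treats this as four
stages — concept recognition, restricted ontology search, match curation
and selection, and RDF rewriting — each usable on its own.

## Concept recognition

### Pair encoding

Every labeled column contributes one `(column_id, value_id, label)` triple
per cell, so the pair count is the sum of column sizes. Column ids are
consecutive integers in column order. Value ids are assigned within
*categories* — semantic attribute kinds such as "gene symbol", supplied by
the caller (the fixture generator supplies its ground truth; on real data
the category is the curated attribute kind). Duplicate values inside a
category share one id: similarity learning requires shared ids for shared
values. Two indexing methods are implemented:

* **per-category** — ids restart at 0 inside each category. Ids collide
  across categories, which audibly corrupts the similarity space (distinct
  attributes with overlapping id ranges look identical). Kept because the
  comparison is informative.
* **continuous** (default) — a global counter keeps `(category, value) → id`
  injective.

### The embedding network

Forward pass: look up the column embedding and the value embedding
(both dimension 50 by default), take their dot product, reshape to a
scalar, apply a dense layer and a sigmoid. Training minimizes binary
cross-entropy with Adam (learning rate 0.01, batch 256, 10 epochs by
default) on an 80/20 train/test split (floor on the training share,
seeded shuffle). The network is implemented directly in numpy: the model
is small enough that an explicit gradient (four parameter groups:
two embedding tables, dense weight, dense bias) is clearer and faster to
audit than a framework graph, and training on the default bundle takes
under a second on one CPU. A sigmoid closes the dense layer; 0.5 is the
classification threshold. Unknown ids at inference raise rather than
falling back to a default embedding — silent defaults corrupt similarity
rankings.

Column similarity is the cosine of two column-embedding rows; `top_similar`
ranks all columns by descending similarity with ties broken by column id,
and includes the query itself (similarity 1.0 up to rounding).

### Name-only classifier

Column titles are encoded as fixed-width vectors of ASCII codes, zero-padded
to the longest name in the corpus; non-ASCII characters map to 0 (the
scheme is ASCII-only and collisions with padding are acceptable at corpus
scale). The classifier is a single-hidden-layer (64 unit) feed-forward
network (scikit-learn `MLPClassifier`, seeded); inputs are scaled by 1/127.

### Corpus expansion

Real datasets offer too few column names to train on, so the name list is
expanded twice:

1. **Heuristic expansion** — for every name: lowercase, uppercase,
   space→underscore and underscore→space forms, applied to closure so that
   re-expanding the output adds nothing; plus `n_recombinations` random
   two-token concatenations (no separator) drawn from the pooled token
   vocabulary, seeded. The default of 900 recombinations puts a
   three-dataset corpus near one thousand names; the count is a parameter
   because nothing forces a particular value.
2. **Generative expansion** — a character-level generative model trained on
   the heuristic corpus. Implemented as an order-3 character Markov sampler
   with back-off and temperature; any character-level sequence sampler with
   reproducible seeded output satisfies the contract, and the Markov model
   keeps the dependency footprint at numpy alone.

Generated strings are labeled by a vocabulary rule — positive iff every
space/underscore token appears in the original token vocabulary — standing
in for manual curation; a curator callback always overrides the rule.
Incoherent character runs (the classic false-positive failure mode of the
name-only model) are labeled negative by construction.

## Ontology search and curation

The term repository is a pluggable interface. The deterministic in-memory
index (JSON term records, insertion-ordered results) is the offline
implementation; a thin REST client for a live biomedical ontology portal
exists behind an explicit `--live` flag and is never needed for tests. Two
restrictions are supported, both monotone (they only remove results):

* **longest match** — only terms whose normalized label contains the full
  normalized search key survive;
* **ontology filter** — only terms from a given acronym list survive.
  The list comes either from an explicit choice, from a *frequency
  distribution* (count matches per ontology; select ontologies whose count
  meets a threshold, where the threshold is explicit or the mode of the
  per-ontology count multiset, ties resolved toward the smaller count so
  selection never narrows artificially), or from the recognized concept via
  an ontology-list provider (offline: ontologies whose description mentions
  the concept).

Matches are curated into FULL (normalized labels equal), SEMI (token sets
intersect) and NONE (disjoint) — an auto-suggestion only; a curator verdict
always wins, since description-appropriateness is a human judgment. The
first FULL match in repository order becomes the column's property;
columns without one keep their generic predicate.

## RDF enhancement

Input and output are N-Quads. Each property-map entry generates one SPARQL
Update statement (`DELETE { GRAPH ?g { ?s <old> ?o } } INSERT { GRAPH ?g
{ ?s <new> ?o } } WHERE ...`), preserving graph membership, subjects and
objects; a set class IRI generates one statement typing the subjects of
mapped predicates (all subjects when the map is empty). Statements are
applied through rdflib's update engine and can be exported as a single
SPARQL Update document for an external store. Rewrites conserve the quad
count and are idempotent; a rewrite whose old predicate is absent is a
warning no-op. Original generic triples are deleted on rewrite (this is
what "covered/replaced" means in the coverage metric); keeping them
alongside would double-count properties.

## Metrics

* **Coverage** = 100 · matched columns / total columns, per dataset.
  Rounding is half-up with a caller-chosen number of decimals (default:
  integer percent; one decimal available where the convention in published
  tables keeps it, e.g. 8/11 → 72.7). The formatted form drops a trailing
  ".0". No single zero-argument rounding rule reproduces mixed-precision
  published tables (36.73% prints as 37 while 72.72% prints as 72.7), so
  precision is an explicit parameter rather than a heuristic.
* **Average coverage** = arithmetic mean of the per-dataset percentages,
  rounded half-up to one decimal.
* **Completeness** = 100 · full matches / total matches, two decimals,
  undefined (an error) when there are no matches.
* **Quality tally** per enhanced dataset: broad terminology, ontology
  hijacking and missing definition are curator flags on mapped columns;
  undefined terminology is computed, not curated, as total columns minus
  mapped columns, so UT + TAP = TP holds by construction.

## Synthetic fixtures

The generator emulates gene-dataset structure at pattern level: three
datasets, 1000 rows by default, ~16 columns spread over 12 concepts.
Positive concepts (gene identifier, gene symbol, gene name) span several
columns across datasets, all sampling with replacement from one shared
value pool (default pool size: one tenth of the row count, so values repeat
and concept-mates overlap heavily); negative concepts (dates, chromosomal
coordinates and bands, accession and literature identifiers, organism
names) are single columns with private pools. Value patterns: symbols are
2–6 uppercase alphanumerics; numeric identifiers are consecutive integers
from a random base; names are two lowercase words; dates are ISO
`YYYY-MM-DD`; coordinates are integers up to 2.5·10⁸; bands look like
`7q31.2`. The mock ontology index gives every positive-concept column a
FULL-matchable property in a gene ontology (plus SEMI terms and distractors
in two non-gene ontologies), so the gene ontology wins the frequency
analysis and the quality tally's UT count equals the number of negative
columns by ground truth.

What the fixtures do **not** emulate: real nomenclature statistics
(symbol/name morphology beyond pattern level), cross-concept value
collisions (a symbol that is also a valid name), missing cells, multi-value
cells, and the scale of real interaction files (hundreds of MB). Passing
tests therefore demonstrate that the machinery recovers planted structure
under clean conditions, not that real datasets reach any particular
accuracy; published accuracy on real corpora is service- and
version-dependent and is out of scope by design.

## Sizes, determinism, degenerate inputs

Default problem sizes (1000 rows → 16 000 pairs, embedding dim 50, 10
epochs, 100 evaluation subsamples at 50%) keep a full pipeline run in
seconds on one CPU while leaving the planted signal non-trivial. All
randomness flows through `numpy.random.default_rng(seed)`; fixed seeds give
byte-identical fixtures, identical training trajectories and identical
evaluation reports. Degenerate inputs fail loudly: ragged rows name the row
number, empty corpora/match lists/test sets raise, single-class training
data raises, 0/0 precision is reported as undefined rather than 0.

## Known limitations

Binary recognition of a single concept only (multi-class recognition would
need retraining and new labels); the name-only model underperforms by
construction and is kept for comparison; curation categories beyond exact
label equality require a human in the loop; the live repository client is
deliberately minimal (search only, no paging beyond the page limit, no
caching).
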