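# Methods

This note documents the models and procedures implemented in `seqgo`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Ontology handling

The Gene Ontology is modeled as a DAG of classes in three namespaces (MFO,
BPO, CCO) with typed relations. By default **every** relation type present
in the OBO file is traversed (`is_a`, `part_of`, and any others), because
cross-namespace links such as a `part_of` edge from a molecular-function
class to a biological-process class carry real annotation signal; a
whitelist (e.g. `{is_a, part_of}`) can be supplied for the stricter
convention. Whether regulates-type relations should be traversed is a known
point of divergence between pipelines; the all-relations default errs on
the inclusive side and is configurable.

Two ancestor-closure modes are supported everywhere:
`whole_ontology` follows all traversed edges including cross-namespace
ones; `per_subontology` ignores edges whose endpoints lie in different
namespaces, reproducing the CAFA3 assessment's convention. Per-sub-ontology
ancestor sets are always subsets of whole-ontology sets.

Propagation (the true-path rule) closes each protein's annotation set under
ancestors; it is idempotent and extensive. Annotations to obsolete classes
are remapped through `replaced_by` when available, otherwise dropped with a
warning; `alt_id`s resolve silently to their primary id. Obsolete terms are
retained in the parsed ontology (flagged) but never traversed. Classes are
ordered lexicographically by id wherever an order matters, for
reproducibility.

**Information content.** `IC(c) = −ln Pr(c | P(c))` with `P(c)` the set of
direct parents. The conditional is estimated from a propagated training
corpus as (proteins annotated with `c`) / (proteins annotated with *all*
direct parents of `c`) — the conjunction, since `P(c)` is a set. Add-one
smoothing (default on) keeps classes that appear only in test data finite;
with smoothing off, classes absent from the corpus are omitted and a
zero-support parent conjunction is an error. The natural logarithm is used;
log base only rescales Smin, and the natural log is the common convention.
Roots have IC 0.

## Baseline predictors

All baselines consume a *propagated* training corpus, so transferred class
sets are automatically ancestor-closed. Similarity hits are read from
BLAST/DIAMOND tabular output, filtered at e-value ≤ 0.001, deduplicated to
the maximum bitscore per (query, subject) pair, and self-hits dropped. Hits
whose subject carries no training annotation are excluded from both the
numerator and the denominator of the transfer formulas: their annotation
set is unknown (missing), which is not evidence of absence. When several
hits tie at the maximal bitscore in best-hit transfer, a class scores 1 if
any of them carries it — the max over score products already implies this.

## Convolutional classifier

* Input: one-hot, 21 rows (alphabet fixed alphabetically as
  `ACDEFGHIKLMNPQRSTVWY` plus one unknown row for B, J, O, U, X, Z, `*`
  and anything else), width 2000, zero-padded.
* Convolutions: one bank per filter length (default 8, 16, …, 128; 512
  filters each), valid padding, stride 1, **no activation function** —
  global max pooling over positions immediately follows, so each filter
  reports only its best match anywhere in the sequence. This is what makes
  a filter interpretable as a motif detector.
* Classifier: the pooled features (default 16 × 512 = 8192) feed one fully
  connected sigmoid layer, one unit per selected GO class — a flat
  multi-label classifier with no hierarchy. With dense depth > 1,
  intermediate layers use ReLU (with depth 1 there are no intermediate
  layers and ReLU is moot).
* Training: binary cross-entropy, Adam at learning rate 3e-4 (default), a
  random 10% validation split drawn from the config seed, early stopping
  when validation loss fails to improve for `patience` epochs (default 6),
  best-validation weights restored. Batch size 32 and at most 100 epochs by
  default; all conventional values, all configurable.
* Chunking: sequences longer than 2000 residues are split into
  non-overlapping windows whose concatenation is the original sequence, and
  chunk scores are merged by elementwise maximum — consistent with the
  max-pooling semantics (a motif in any chunk should fire). An optional
  overlap of (longest filter − 1) residues catches boundary-spanning
  motifs; off by default as the simplest reading.
* Class selection: classes with ≥ 50 propagated training annotations, in
  lexicographic order; this list is the output dimension. A single model
  covers all three sub-ontologies.
* No score propagation to ancestors is applied by default (the classifier
  is flat); `propagate_scores` provides the post-hoc parent-max closure and
  the evaluation applies it to both predictions and truth so that both
  sides live in the same closed space.

The implementation is plain numpy (im2col convolution, manual backprop
through the pooling argmax, Adam). Training is bit-reproducible for a fixed
(seed, data, config) in one environment. Batch composition changes the
zero-padding width; scores are mathematically invariant to padding (every
sequence in a batch retains at least one all-zero window per filter bank)
but differ at float32 rounding level (~1e-7) across widths, so prediction
equality across batchings is asserted at 1e-5.

**Hyperparameter grid.** The documented search space — five filter-length
sets (8…32 up to 8…512 in steps of 8), filter counts {32, 64, 128, 256,
512}, dense depth {1, 2, 3} — enumerates 75 combinations;
`hyperparameter_grid()` reproduces it. The package does not re-run this
search (it is GPU-scale); the grid is exposed for arithmetic checks and for
users with the hardware.

**Filter interpretation.** For any sequence, each filter's best-scoring
window (valid convolution over the unpadded sequence, first position on
ties) is extractable; filters are associated to a class by their weight
into that class's output unit, which is well-defined for the flat
classifier.

## Ensemble

`S = α·S_similarity + (1−α)·S_cnn` per protein and class, with α chosen
per the class's namespace (defaults MFO 0.55, BPO 0.59, CCO 0.46). A class
scored by only one component contributes 0 for the other, **except** that a
protein with no similarity hits at all keeps its CNN scores unscaled:
otherwise a novel protein without annotated homologs — precisely the case
the motif path exists for — would have every score shrunk by (1−α). The
strict weighted sum is available behind a flag. α is tuned per
sub-ontology by maximizing validation Fmax over the grid {0, 0.01, …, 1}
(two-decimal α values are exactly representable on this grid), ties broken
toward smaller α. Because the grid contains both endpoints, the tuned
ensemble's validation Fmax dominates both components *per sub-ontology*;
no such guarantee exists for Fmax pooled across namespaces, and the
package reports the per-namespace comparison.

## Evaluation

Predicted sets are `P_i(t) = {f : score > t}` — strict inequality, so
threshold 1.00 always yields empty sets and is skipped by the m(t) > 0
rule. Average precision is taken over the m(t) proteins with at least one
prediction, average recall over all n benchmark proteins; the benchmark
protein set is exactly the truth corpus (predictions for other proteins
are ignored). If no threshold yields any prediction, Fmax is defined as 0
with a warning rather than an error, so degenerate baselines on tiny sets
do not crash. Smin has no m(t) rule and is minimized over the full grid.
AUPR is micro-averaged over the (protein, class) pair universe restricted
to classes appearing in the truth or the predictions — the pair universe
is not standardized in the literature, so this choice is documented and an
all-ontology universe would only add always-negative pairs; integration is
trapezoidal at every distinct score with a (recall 0, precision 1) anchor.

The vectorized implementations agree with direct brute-force translations
of the definitions (explicit loops over proteins × classes × 101
thresholds) to 1e-10 on hundreds of random instances; this agreement is
re-established at every test run and by the acceptance script.

## Synthetic benchmark

The generator emulates the structure the method exploits:

* a toy ontology — one root per namespace, each later term with 1–2
  `is_a` parents among earlier same-namespace terms, and MFO→BPO
  `part_of` edges with probability 0.1 (defaults: 15 terms per namespace);
* distinct random motifs (8–24 residues) for **leaf** classes only,
  mirroring GO's convention of annotating to the most specific class;
  internal classes gain signal purely through propagation, which is what
  makes class selection and IC behave meaningfully;
* 500 proteins of 100–400 residues, uniform background composition, each
  carrying 1–3 leaf classes with the corresponding motifs planted once at
  non-overlapping positions and mutated at 2% per residue;
* a similarity table derived from shared leaf annotations
  (bitscore = 40 × shared + Normal(0, 5) truncated at 25, e-value
  `10^(−bitscore/10)`, 1% background hits, 50 hits per query) — a stand-in
  for a real aligner run so tests need no external search tool.

What it does **not** emulate: realistic amino-acid composition, indels,
motif families with internal variability, realistic bitscore/e-value
statistics, annotation noise and incompleteness, or the heavy class
imbalance and scale of real corpora (tens of thousands of proteins,
thousands of classes). Passing the benchmark therefore demonstrates that
the implementation learns and evaluates correctly under its own modeling
assumptions — not that it reaches any particular accuracy on real data.

**End-to-end experiment** (`pipeline.run_synthetic_benchmark`): the 500
proteins are split 400/100 train/test, and 10% of the training proteins
are held back from CNN training as the ensemble-validation split
(360/40/100). Classes are selected at the ≥ 50-annotation threshold on the
CNN-training corpus. The experiment's CNN uses filter lengths (8, 16) with
64 filters each, learning rate 1e-3, batch 32, at most 100 epochs with
patience 6 — filters of length 8 and 16 are ample for planted motifs of
8–24 residues, and this size trains in seconds on one CPU; the full
16-bank × 512-filter default architecture is exercised analytically (its
training is GPU territory and out of scope). The CNN's held-out Fmax is
computed against truth restricted to the model's class universe: a
fixed-output classifier benchmarked on classes it cannot emit would
measure coverage arithmetic, not learning. The predictor comparison
(naive / homology / CNN / ensemble) uses the unrestricted truth, one
common universe for all.

**Filter-motif recovery**: for each test protein and each of its true
model classes, the 10 filters with the largest dense weight into that
class are located in the sequence; the reported rate is the fraction of
(protein, class) pairs for which at least one of those filters' best
windows overlaps a planted motif interval. Rates near 1.0 on the defaults
show the filters are genuinely locating the planted signal rather than
background.

## Numerical and degenerate-input conventions

* Scores are validated to [0, 1] at container construction; serialized
  predictions are rounded to 3 decimals and scores below 0.01 omitted
  (the threshold grid's resolution with headroom).
* Readers fail with line numbers on malformed input; e-value filtering,
  per-query bitscore sorting (ties broken by subject id) and duplicate-pair
  deduplication happen at load time, making re-serialization idempotent.
* Argmax/argmin ties (pooling positions, Fmax/Smin thresholds, α grid)
  resolve to the first/smallest candidate.
* Empty corpora, unpropagated inputs where propagation is required, empty
  term lists, sequences shorter than the smallest filter, and unknown
  ontology ids all raise immediately with specific messages.

## Known limitations

* The numpy CNN is CPU-bound and intended for desk-scale experiments;
  training the full 8192-filter model on a real corpus is out of reach
  without an accelerator framework.
* Similarity search itself is external: the package consumes tabular
  output (the conventional invocation is a DIAMOND/BLAST run with
  `--outfmt 6` and e-value 0.001) and the synthetic table stands in for it
  during tests.
* Per-class ensemble weights, hierarchical classifiers, term-centric and
  weighted-Fmax evaluation variants, and bootstrap confidence intervals
  are not implemented.
* CAFA target-id mapping is left to a user-supplied table in the
  submission writer.
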