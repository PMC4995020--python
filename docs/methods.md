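# Methods

## Model and assumptions

The detector treats conservation as a *positional frequency* signal. For a
dataset *S* of *n* protein sequences, the frequency of a k-mer is the number
of distinct sequences containing it at least once; a sequence's k-mer
profile lays those frequencies down at the k-mers' originating indices. The
working assumption is that a region conserved across a family recurs nearly
verbatim in many dataset sequences, so its k-mers reach frequencies far
above the ~1 expected for random k-mers over a 20-letter alphabet
(a specific 6-mer collides between two random flanks with probability about
|flank|²/20⁶ per pair). The assumption fails, and the method with it, when a
conserved region is present in too few dataset sequences to lift its
frequencies, or when conservation is maintained with many substitutions
(exact k-mer matching sees only identity, not similarity).

Classification is per index: the feature vector for index *i* is the window
of 2w + 1 profile values centred on *i*, and a Random Subspace ensemble of
decision trees votes conserved / not conserved. Trees suit the problem
because the features are integer counts, the decision surface is
axis-aligned (thresholds on frequencies), and different window positions
need different thresholds; the subspace ensemble counters the tendency of a
single tree to overreact to short-lived frequency spikes. Maximal runs of
conserved indices are reported as conserved regions.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| k | 6 | residues | k-mer length; smaller k inflates random collisions, larger k loses tolerance to substitutions |
| w | 10 | indices | half-window; feature vector length 2w + 1 = 21 |
| MSS | 100 | instances | minimum node size eligible for splitting (pre-pruning strength) |
| max_features | 7 | features | features drawn (uniformly, without replacement) per tree |
| n_trees | 100 | trees | ensemble size; not fixed by the method's description, set to standard Random Subspace practice |
| seed | 0 | — | drives subset draws and tree randomness; fixed (data, config, seed) reproduces the ensemble exactly |

k, w, MSS and max_features defaults are the method's published operating
point. Rows are never bootstrapped: this is Random Subspace, not Random
Forest. Tree impurity is Gini (the scikit-learn default) and is recorded in
the model file's metadata; no class-imbalance correction is applied by
default, with a `class_weight` pass-through for datasets where the
conserved fraction is extreme.

## Numerical and representational choices

* **Coordinates** are 0-based half-open everywhere internally; the
  annotation reader and the GFF3 writer convert at the boundary. The
  1-based-inclusive dialect is supported at the reader because public
  domain-interval dumps use both conventions.
* **Profile tail**: only |s| − k + 1 indices originate a k-mer. The profile
  keeps the sequence's full length with the last k − 1 entries set to 0, and
  `valid_len` marks the boundary. Instances are still generated for tail
  indices — their left windows carry signal. Sequences shorter than k get
  all-zero profiles.
* **Frequencies are distinct-sequence counts**; repeated occurrences within
  one sequence collapse to a single membership in both the serial hash
  passes and the map/shuffle/reduce mode.
* **Parallel mode** reproduces the grouping semantics of the two-pass hash
  as explicit stages — map emits (k-mer → position, sequence id) records
  per sequence chunk, a shuffle groups by k-mer, the first reduce counts
  distinct sequences and re-keys by sequence id, the second assembles each
  profile — and is bit-for-bit identical to the serial path for every
  worker count. It is a single-machine parallelization, not a distributed
  framework.
* **Vote tie-break**: with an even number of trees an exact tie resolves to
  non-conserved — the conservative call, trading recall for fewer false
  positive regions.
* **Undefined ratios** (SN with no reference-positive indices, SP with no
  reference-negative indices) are reported as NaN with a warning, never as
  0 or 1. Report percentages are rounded half-up to one decimal; the
  aggregate Average row is the arithmetic mean of the per-set rounded
  percentages, rounded the same way.
* **Non-standard residues** (X, B, Z, U, O, `*`) are kept as literal
  characters: the method is lexical, and removing them would shift every
  downstream index. Exact-duplicate sequence removal exists behind a flag,
  default off; it is dataset preparation, not part of the method.
* **Degenerate training data** (a single class) yields a constant predictor
  with a logged warning rather than an error, so pipelines on pathological
  inputs fail loudly but late.

## Synthetic families: what they emulate and what they do not

`synthetic.generate` draws, per family, one master domain uniformly over the
20 standard letters and builds each sequence as random left flank + a noisy
domain copy + random right flank. Noise is i.i.d. per-residue substitution
at `mutation_rate`, the replacement drawn uniformly from the other letters;
flank lengths are uniform on [flank_len/2, 3·flank_len/2]. Truth intervals
are the exact implanted positions. Under this model the probability that a
domain k-mer survives unmutated is (1 − p)^k (≈ 0.735 at p = 0.05, k = 6),
so interior domain positions have expected frequency ≈ n_seqs·(1 − p)^k
while flank positions sit at ≈ 1 — exactly the contrast the classifier
needs, with realistic within-window correlation structure.

The defaults (200 sequences per family, domain 60, flanks ~80, 5%
substitution, 5 families) are the package's reference study condition for
the end-to-end benchmark. `make_benchmark` partitions either by withholding
whole families (no master domain shared between train and test — measures
de novo detection) or, with `holdout_families=0`, by a random 80/20
sequence split (measures retrieval of already-seen domains).

What the simulator does **not** emulate: insertions and deletions (the
conservation signal here is strictly positional), substitution preferences
(no BLOSUM weighting — every mis-substitution is equally disruptive, which
if anything understates real k-mer survival between related sequences),
length and composition heterogeneity of real proteomes, and partial or
nested domains. Passing the synthetic benchmark therefore shows the
pipeline recovers frequency-contrast conservation under substitution noise;
it does not certify performance on real, indel-rich families, where
per-index agreement with curated domain databases is known to be far below
the synthetic ceiling.

## Design choices that were genuinely open

* **Ensemble size** is not fixed by the method's published description;
  100 trees is standard Random Subspace practice and is recorded in every
  model file.
* **Tail instances** (last k − 1 indices) are classified rather than
  skipped, since their windows still contain informative left context.
* **Region post-filtering**: regions are defined purely as maximal runs; a
  minimum-length filter exists (`filter_min_length`, `--min-region-length`)
  but defaults to off, because any cutoff is a data-dependent policy, not
  part of the region definition.
* **Model persistence** uses a joblib archive embedding a format version,
  k, w, the full configuration and the trees; loading any other version
  fails explicitly rather than guessing.

## Problem sizes used in the test suite

The suite exercises exact-oracle equivalence on hundreds of small random
sequence sets (n ≤ 30, |s| ≤ 60, k ≤ 4) against a naive
substring-membership scan; the parallel contract on a 500-sequence
simulated set at k = 6 for 1/2/4/8 workers; and the end-to-end benchmark at
the reference study condition above (1,000 sequences, ~220 k instances),
which completes in well under a minute on one core. These sizes were chosen
as the smallest at which each property is meaningfully tested; the
generator's statistical behaviour is size-stable, so nothing in the method
depends on them.

## Known limitations

* Sensitivity to the dataset itself: prediction quality on a query set
  depends on how many copies of each conserved region that set (or the
  stored frequency table used with `--table`) contains.
* Exact matching only: heavily diverged families with conserved structure
  but low sequence identity are invisible.
* Per-index evaluation: a prediction offset by a few residues is penalized
  index-by-index; no boundary-distance or per-domain matching is
  implemented.
* Memory: the k-mer hash table is in-memory; k is capped at 12.
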