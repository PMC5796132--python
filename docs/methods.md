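# Methods

## Problem setting

Each protein functional family defines an independent binary
classification problem: given a query sequence, is it a member? Four
predictors are compared — a local-alignment similarity search and three
classifiers over fixed-length physicochemical descriptors — along two
axes: identification accuracy on held-out family members, and the false
discovery rate when scanning an entire proteome for one family.

## Dataset construction

Family members (positives) are deduplicated by exact sequence string,
randomly permuted under the configured seed and dealt round-robin into
training, testing and independent sets, so the three positive counts
differ by at most one. Negatives come from a pool of coherent, unrelated
sequence groups ("pseudo-Pfam" families). A group containing any member
of the positive family is excluded entirely; from each remaining group
three representatives are drawn at random and dealt one each to
training, testing and independent, in that order (groups with fewer than
three members contribute what they have, dealt in the same order, rather
than being discarded — scarce negatives are valuable). The triple is
validated for pairwise disjointness by sequence string and for both
classes being present in every set; violations are configuration errors,
never silently patched. One integer seed drives a single pseudo-random
stream for the permutation and all negative draws, so a triple is a pure
function of its inputs and seed.

The testing set is used exclusively for hyperparameter tuning. The final
model is re-trained on training+testing with the tuned parameters and
evaluated exactly once on the independent set.

## CTD features

Sequences are encoded as 188 real numbers: 20 amino-acid composition
fractions, then for each of eight properties (hydrophobicity, normalized
van der Waals volume, polarity, polarizability, charge, secondary
structure, solvent accessibility, surface tension) a 21-value CTD block.
Each property partitions the 20 standard residues into three groups; the
partitions are the canonical tables of the CTD descriptor literature and
ship as a versioned TSV (`funcbench/data/ctd_groups.tsv`) whose row
order freezes the vector layout — logic never hard-codes a group.

* **Composition**: fraction of residues in each group (3 values, sum 1).
* **Transition**: for each unordered group pair, the number of adjacent
  residue pairs whose members lie in the two different groups, divided by
  the total number of adjacent pairs (3 values, sum ≤ 1).
* **Distribution**: for each group with n occurrences at 1-based
  positions p₁ < … < pₙ in a length-L sequence, the five percentages
  100·p_j/L at j = 1, ⌈n/4⌉, ⌈n/2⌉, ⌈3n/4⌉, n (minimum index 1); an
  absent group reports five zeros. The five values are nondecreasing and
  the last equals 100·pₙ/L.

Ambiguity codes (B, J, O, U, X, Z) are tolerated on input and skipped by
the encoder: they join no group, no adjacent pair, and do not count
toward L. This keeps every composition block summing exactly to 1. An
alternative layout treating amino-acid composition as a ninth 21-value
CTD block would be a one-table change; the 20 + 8×21 layout is the one
frozen here.

Feature matrices are min-max scaled to [0,1] with parameters fitted on
the training matrix only (constant columns map to 0); distance-based
classifiers would otherwise be dominated by the distribution block's
percent scale.

## Classifiers and tuning

* **KNN**: Euclidean k-nearest neighbors on scaled features, majority
  vote; grid k ∈ {1,3,5,7,9,11} (capped at the training size).
* **PNN**: Parzen/Specht kernel density with one spherical Gaussian
  width σ shared by both classes; class score
  g_c(x) = (1/n_c)·Σ exp(−‖x−t_i‖²/2σ²). Implemented with log-sum-exp so
  that as σ→0 the argmax degenerates exactly to 1-nearest-neighbor
  (asserted by test) instead of underflowing to a tie. Grid: σ over
  {0.01, 0.03, 0.1, 0.3, 1, 3, 10} × the median pairwise training
  distance.
* **SVM**: RBF kernel, grids C ∈ {0.1, 1, 10, 100},
  γ ∈ {0.001, 0.01, 0.1, 1}; an optional class-weight knob exists but
  defaults to off — the benchmark runs on the data as constructed, with
  no reweighting of the ≈3-negatives-per-group imbalance.

Tuning maximizes MCC on the testing set; an undefined MCC (degenerate
prediction) ranks below any defined value; ties resolve by grid order.
The full score table is retained for audit. Tie rules at prediction time
(KNN even vote, PNN equal densities) resolve to the negative class —
conservative for false-discovery control.

## Similarity baseline

A query is family-positive when any reference sequence aligns with
E ≤ 0.001 and identity ≥ 40%. The per-family reference database holds the
deduplicated *positive* training+testing sequences; for proteome scans it
holds all known family sequences, including the independent set, since a
scan models annotation with everything known about the family.

The internal backend computes optimal local alignments (BLOSUM62, gap
open 11 / extend 1 in BLAST's convention, i.e. a length-k gap costs
11 + k) via Biopython's pairwise aligner, and converts raw scores to
E-values with the Karlin–Altschul formula using the published gapped
parameters λ = 0.267, K = 0.041, m = query length, n = total database
residues. Effective-length edge corrections are omitted: at per-family
database scale they shift E by a modest constant factor and no decision
near the cutoffs depends on them. Identity is identical aligned pairs
over alignment length including gap columns (the convention of the
external tool), and it is the identity of the local alignment, not of
the full query. Scoring is two-phase for speed: a score-only pass
computes E for every subject, and tracebacks (needed only for identity)
run just for subjects passing the E cutoff. The optional external
backend wraps NCBI `blastp -evalue 0.001` with composition-based score
adjustment disabled, post-filtering at 40% identity; the two backends
are required to agree on ≥95% of calls, not on exact scores.

Residues J, O and U, absent from the BLOSUM62 table, are mapped to X for
alignment only.

## Metrics and comparison

SE, SP and ACC are percentages; MCC lies in [−1,1]. A metric whose
denominator (or any MCC factor) is zero is *undefined* and carried as
NaN — never coerced to 0, which would bias medians — and dropped
pairwise in aggregation. Methods are compared per metric by a paired
two-sided Wilcoxon signed-rank test across families (configurable to a
paired t-test), requiring at least 6 families with defined values per
pair; identical columns short-circuit to p = 1.

## Synthetic data

The generator is the study's input model, not a tuning dial:

* **Families**: one ancestor drawn from a residue-frequency profile
  (default: average composition of reviewed proteins, not uniform);
  members derive independently by per-site substitution — always to a
  *different* residue, so the rate is the observed per-site change
  probability — plus single-residue indels (default rate 0.01, no
  geometric extension, keeping the identity↔rate mapping analyzable).
  Two members agree at a site when neither mutated, so expected pairwise
  identity ≈ (1−r)²; r = 0.15 gives ≈72% identity, a strongly conserved
  family, and r = 0.45 a remote-homology regime. Default family size 60,
  lengths uniform in 120–220 residues — desk-scale stand-ins for curated
  keyword families.
* **Negative pools**: 20 groups by default, each its own family with a
  Dirichlet-perturbed composition bias (concentration 120 × background),
  so negatives carry realistic but not trivially separable composition
  signal.
* **Proteomes**: shuffled mixtures of background sequences and freshly
  derived family members ("cousins", never copies of benchmark records),
  with hidden truth labels. Scan recall is therefore a genuine
  generalization measurement, not memorization. The audit default is
  2,000 sequences with 5% planted.

What the generator does **not** emulate: domain architectures, repeats,
low-complexity regions, real keyword semantics, shared domains between
families, and inter-family homology. Consequently the synthetic
benchmark at r = 0.15 is easy — all four methods reach near-perfect
independent-set metrics — and passing it demonstrates correctness of the
pipeline's plumbing and statistics, not real-data ranking of the
algorithms. On real families the feature classifiers and the alignment
baseline diverge much more sharply.

## Numerical and reproducibility choices

* All randomness flows from one master seed through spawned
  `numpy.random.SeedSequence` children (kept below 2³¹); every derived
  seed and every tuned parameter is written to the run manifest, which
  suffices to replay any family.
* Reports render percentages at 2 decimal places; the JSON output keeps
  full precision. Reruns with one config are byte-identical.
* Degenerate inputs fail loudly: fewer than 3 positives, no eligible
  negative group, a set missing one class, an unencodable sequence, a
  single-class training set and an empty scan set are all errors.

## Known limitations

* The internal aligner is exhaustive (no word seeding); fine at
  per-family database scale, not meant for proteome-vs-proteome search.
* E-values use fixed gapped parameters for BLOSUM62/11-1 only; other
  matrices would need their own (λ, K).
* Binary, single-label problems only; no multi-class metrics, no
  probability calibration, no profile/PSSM features.
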