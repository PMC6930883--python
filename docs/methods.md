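# Methods

## Scope and model

`cnvrules` classifies tumor samples into copy-number-defined states from
SNP-array signals. The quantity being modelled is a per-sample categorical
state (MACROD2 deletion status, or Dukes stage) assumed to be expressed in
the array's log R ratio (LRR) and B allele frequency (BAF) channels through
integer copy number at a contiguous block of loci. The pipeline is
deliberately modular: a synthetic-data generator with known ground truth, an
information-theoretic feature-selection stack, cross-validated evaluation,
and two classifier backends (a linear margin classifier for performance, an
ordered rule list for interpretation).

## Synthetic cohorts

The generator (`simdata`) emulates an Illumina-style tumor array cohort:

* **Copy number.** Each sample carries integer copy number in {0, 1, 2} per
  marker. A designated contiguous *gene region* (the MACROD2 proxy, placed
  on chromosome 20 at ~14.5 Mb in the marker map) is diploid in wild-type
  samples; heterozygous-deletion samples carry CN = 1 and homozygous samples
  CN = 0 on a random contiguous sub-segment. The segment length is uniform
  on [0.6·R, R] for an R-marker region: CNVs are segmental, and the 0.6
  floor guarantees a shared core of markers deleted in *every* deleted
  sample, which makes the three states exactly separable on those markers
  when noise vanishes — the property the recovery tests rely on.
* **Background CNVs.** Outside the region, segmental deletions (geometric
  lengths, mean 5 markers; CN 1 with prob. 0.8, else 0) are sprinkled so
  that ~1 % of off-region markers per sample are altered. They never touch
  the gene region, so state labels recomputed from the emitted copy numbers
  always match the intended classes. Their role is to give feature selection
  realistic distractors.
* **LRR emission.** Gaussian around a copy-number-dependent center,
  defaults 0.0 / −0.45 / −1.0 for CN 2/1/0 with sd 0.15. The attenuated
  (non-ideal) response reflects tumor arrays, where practical deletion
  thresholds sit near −0.25 to −0.5 rather than at the theoretical
  log₂(1/2) = −1. All centers and the sd are configurable.
* **BAF emission.** For CN = 2 the genotype is drawn Hardy–Weinberg from a
  per-marker B-allele frequency (uniform on [0.1, 0.9] unless supplied),
  giving centers 0 / 0.5 / 1 plus clipped Gaussian noise (sd 0.03); CN = 1
  leaves a single allele (center 0 or 1); CN = 0 has no allele to hybridize
  and is modelled as uniform noise on [0, 1].
* **Class sizes.** Defaults reproduce the 651-tumor cohort composition the
  package models: 441/137/73 for the three MACROD2 states and 60/208/297/86
  for Dukes stages A–D. Stage labels are not derivable from a single gene
  state, so the Dukes generator uses a stylized monotone-burden scheme
  (stage A deletes none of the region, B a third, C two thirds, D all of
  it); this preserves imbalance and separability through the same CNV
  channel but is *not* a biological model of staging.

What the generator does **not** emulate: raw X/Y intensities, GC waves,
subclonal (fractional) copy numbers, genotyping error, or linkage structure
between markers. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and self-consistent, not that the published
cohort's accuracies would be reproduced on real arrays.

## Feature selection

* **Discretization.** mRMR requires discrete inputs. Each feature is binned
  per-feature into {−1, 0, +1} around mean ± α·sd with α = 1 by default
  (configurable). A constant feature falls wholly in the middle bin. A
  consequence worth knowing: a balanced two-valued feature has |x − μ| = sd
  everywhere and also collapses into the middle bin; in practice continuous
  signals are never exactly balanced-binary.
* **Mutual information** is the plug-in estimate in bits (log₂). With n
  samples the plug-in estimator is biased upward by roughly
  (r−1)(s−1)/(2n ln 2) for an r×s table, so at small n some pure-noise
  features clear the 0.01-bit filter threshold; they carry little relevance
  and are ranked low by mRMR. The threshold applies **strictly** (> 0.01)
  and is configurable.
* **mRMR.** Greedy; difference form (MID) by default, quotient form (MIQ)
  available. Relevance MIs are cached; pairwise redundancy MIs are computed
  lazily, one new column per greedy step, so cost is
  O(top_n · survivors · n) rather than quadratic in survivors up front.
  Ties break by panel order, making the ranking deterministic.

## Evaluation

* **Cross-validation** is stratified 10-fold by default (a flag disables
  stratification). Stratification is implemented as a shuffled round-robin
  per class with the start offset carried across classes, so per-class and
  overall fold counts both stay within one of each other, and classes
  smaller than k are permitted (with a warning) rather than rejected. The
  fold assignment is computed once per dataset + seed and reused for every
  subset size of an IFS scan, so curve differences reflect feature content
  only.
* **SMOTE** equalizes class sizes by interpolating x + u·(nn − x),
  u ~ U(0,1), between a minority sample and one of its k = 5 nearest
  same-class neighbors. Placement is controlled by `smote_policy`:
  `train_folds_only` (default — no information reaches the held-out fold),
  `before_split` (oversample first, then split; synthetic points share
  generators with test points and measurably inflate scores — provided to
  emulate protocols that rebalance up front, and demonstrated as a test),
  or `none`.
* **Score.** Gorodkin's multiclass MCC (Rk) of the pooled out-of-fold
  confusion matrix, with the convention that a vanishing variance term
  (e.g. a degenerate predictor) scores 0. Per-class accuracies
  (diagonal / row sum) accompany every evaluation; a class with no true
  samples reports NaN.
* **Linear margin classifier.** One binary linear SVM (squared-hinge,
  C = 1) per class against the rest. Raw margins from different binary
  problems are not on a common scale, so each model's decision values pass
  through a sigmoid calibration fitted on its own training data; prediction
  takes the class with the highest calibrated probability, ties broken by
  declared class order. A linear kernel is the conventional and tractable
  choice at SNP-array dimensionality (hundreds of thousands of features).
  One caveat is inherent to one-vs-rest geometry: an intermediate class
  (heterozygous, sitting between wild-type and homozygous along the
  deletion axis) is not always linearly separable *against the union* of
  the others, so out-of-fold perfection is guaranteed only where class
  signatures are exact (e.g. the noiseless shared-core markers).

## Incremental feature selection

Stage 1 evaluates ranked-list prefixes on a step-10 grid starting at k = 10.
The *highest point* is the maximal MCC (smallest k among ties). The
*turning point* formalizes "almost as good but much smaller": the smallest
grid k with MCC ≥ MCC* − δ, δ = 0.05 by default; a chord-distance knee
detector is provided as an alternative strategy. Stage 2 rescans
[1, turning point rounded up to the next step-10 boundary] at step 1, and
its highest point is the final optimum. When the ranked list is shorter than
the coarse step, the grid degenerates to a single evaluation at the list
length.

## Rule learning

The ordered-rule learner follows the RIPPER recipe on continuous features:

* classes processed smallest-first by default (`fixed` ordering available);
  the last class becomes the conditionless default rule;
* rules grow greedily by FOIL information gain
  p·(log₂ p/(p+n) − log₂ P/(P+N)) on a 2/3 grow split, with candidate
  thresholds at midpoints between sorted distinct values (deterministic and
  scale-free), until no covered negatives remain or no positive gain exists;
* pruning drops a final run of conditions to maximize (p − n)/(p + n) on the
  held-out prune split, shorter rules winning ties;
* acceptance stops when the total description length (a 0.5-weighted theory
  term per rule plus binomial-coded exceptions) exceeds the best seen by 64
  bits, when a rule covers fewer than 2 samples, or when a rule is wrong on
  at least half its coverage;
* two optimization rounds then let each rule compete against a freshly
  grown replacement and a revised extension, scored by total description
  length.

Rule **support** and **accuracy** are evaluated *independently per rule*
(the percentage of all samples satisfying the conditions, and the fraction
of those with the consequent label), because published decision lists of
this kind report overlapping supports that cannot arise from sequential
coverage; the default rule is scored on samples matched by no conditioned
rule. A `sequential=True` mode scores each rule only on the samples it
actually fires on, under which a noiselessly learned list is 100 % accurate
rule-by-rule. Whether to score on original or SMOTE-augmented samples is a
flag; the default is original samples.

## Numerical and design choices

* All randomness flows from integer seeds through `numpy` `SeedSequence`
  streams (separate streams for copy number, LRR, BAF, allele frequencies,
  fold assignment, SMOTE per fold), so equal seeds give bit-identical
  outputs and parallel IFS scans match serial ones.
* MI values are clipped at 0 against float round-off; MCC returns 0 on
  degenerate margins; prediction ties break by declared class order.
* Thresholds serialize at full `repr` precision and comparisons are
  inclusive (≤ / ≥); typeset minus signs are normalized to ASCII on parse.
* Default problem sizes in the examples, tests and the acceptance script
  (cohorts of 150–651 samples, panels of 500–2000 markers, rankings scanned
  to depth 60–100) are chosen so that every stage's behavior is exercised at
  realistic class imbalance while a full pipeline run remains a
  desk-interactive computation; the pipeline itself has no architectural
  limit on panel size.

## Known limitations

* The exact survivor counts and optimal subset sizes reported for the
  original 620,901-marker cohort depend on that cohort's data (and on the
  closed-source discretization of the original mRMR program); they are not
  recovered from synthetic data, and the package does not attempt to.
* The rule learner is a faithful re-implementation of the RIPPER procedure,
  not a bit-exact replica of any particular tool (grow/prune splits and
  MDL bookkeeping differ between implementations).
* BAF under CN = 0 is pure uniform noise; real arrays show residual
  structure from cross-hybridization.
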