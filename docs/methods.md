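# Methods

## Model

The pipeline treats organelle membership as a supervised two-class
problem on a proteins × experiments matrix of log2 SILAC ratios. The
working assumption is that members of one cellular structure respond
coordinately to biological perturbations — in each comparative
experiment they are slightly enriched or depleted together relative to
the bulk — while the direction and size of that common shift varies
freely from experiment to experiment. No single experiment needs to
separate the organelle; the classifier integrates many weak,
experiment-specific differences.

Features are used exactly as measured: the matrix is expected in log2
(a flag applies the log transform for raw multiplicative ratios,
demoting non-positive cells to missing with a logged count), no
imputation is ever performed, and per-experiment median centering is
available but off by default, since typical upstream processing
(e.g. MaxQuant) already normalizes each ratio column.

### Missing-value handling

Missing cells are IEEE NaN — a sentinel distinct from every numeric
value that all downstream code branches on explicitly. The trees use
missingness-incorporated-in-attribute (MIA) splits: a candidate split
(feature *f*, threshold θ) is evaluated under both "missing goes left"
and "missing goes right", and the better routing is stored in the node
and reused at prediction. This is deterministic, imputation-free, and
treats missingness as potentially informative, which it is in
proteomics: dropout is abundance-linked, and a contaminant organelle is
systematically less abundant than the targeted structure. A feature
vector that is entirely missing still reaches a leaf through the stored
routings. The original study's classifier is only documented as "not
imputing" missing values; MIA is this package's own concrete contract,
and accuracy statements are therefore made at tolerances, not as
bit-equality with any other implementation.

### Ensemble of balanced forests

One forest: 500 trees, 6 uniformly drawn candidate features per split
(kept fixed rather than recomputed as √p), unlimited depth, bootstrap
samples of size equal to the training set, Gini impurity, thresholds at
midpoints between consecutive distinct observed values. Tie-breaks are
fixed so training is a pure function of (data, seed): equal-gain splits
resolve to the lowest feature index, then lowest threshold, then
missing-left; leaves with tied votes predict the negative class.

The negative class ("everything not in the organelle") is ~25× larger
than a curated positive set, and unbalanced training skews vote-based
scores. The workflow therefore trains k = 10 forests, each with the
same positives and a fresh negative set of equal size drawn uniformly,
without replacement within a draw and independently across draws
(overlap between draws permitted), from the proteins lacking the target
annotation in every supplied catalog. The reported score is the mean of
the k vote fractions; its standard deviation measures sensitivity to
the negative draw.

### Unbiased scores for training proteins

A forest votes almost unanimously for its own training instances, so
resubstitution scores are useless for them (with no signal at all they
would still approach 1). By default each training protein's per-model
score is replaced by that model's out-of-bag vote fraction — the
inbuilt unbiased estimate, costing nothing. The CLI pipeline instead
substitutes 100-fold (configurable) stratified cross-validated scores,
computed separately within each negative draw; the two agree closely
and both remove the memorization artifact.

### Evaluation

Out-of-bag error: each training instance is classified by majority vote
of the trees whose bootstrap excluded it (ties vote negative);
never-out-of-bag instances are excluded and counted. ROC curves use
trapezoidal integration with half credit for ties, so the AUC equals
the midrank Mann–Whitney statistic; an exhaustive pair-counting oracle
verifies this in the tests. Per-experiment shift scans use the
two-sided Welch unequal-variance t-test (group sizes and variances
differ grossly, ≈170 vs ≈4400 in the motivating data); experiments with
fewer than two observed values on either side are flagged untestable.
Feature-count comparisons use the Mann–Whitney test (counts are
discrete and skewed): exact permutation of |U − mn/2| for pooled n ≤ 16,
tie-corrected normal approximation without continuity correction
otherwise, so identical inputs give p = 1 exactly in both regimes.

## Synthetic data

The generator plants the covariation structure the method exploits:

    x[i,e] = mu_i + delta_e·[i in organelle] + delta_e^(m)·[i in module m] + eps

with protein baselines mu_i ~ N(0, baseline_sd²), organelle shifts
delta_e ~ N(0, tau²) shared by all members within an experiment,
analogous shifts for each extra background module, and noise
eps ~ N(0, sigma²). Defaults: 2000 proteins × 45 experiments, 8%
organelle, tau = sigma = 0.5 log2 units (each single experiment is only
weakly informative), baseline_sd = 0.2, two extra background modules of
the organelle's size (so the negative pool contains structured
covariation that is *not* the target), 35% mean missingness, and
organelle abundance scaled to 0.1× the background median (lognormal,
unit log-sd) to mimic contaminant status. Missingness is by default
logistic in standardized log abundance with unit slope, the intercept
calibrated by root finding so the mean per-protein rate matches the
requested value; a missing-completely-at-random (MCAR) mode exists for
calibration work. Rows left with fewer than `min_obs` = 10 observed
cells are dropped, mirroring the real entry filter, and counted.
Requesting a missing rate ≥ 1 − min_obs/n_experiments is rejected as
infeasible.

What the generator does *not* emulate: peptide-level quantitation,
ratio compression, correlated noise between related experiments
(replicates, shared channels), non-Gaussian heavy tails, and any real
biological overlap between compartments. Passing recovery tests
therefore shows the machinery is correct and well calibrated under the
stated model, not that a particular real dataset will reach the same
accuracy.

Null-calibration runs (no planted shift) use the MCAR mode. This is
deliberate: with abundance-linked dropout and a 0.1× organelle, the
missingness pattern alone identifies the organelle, and MIA trees
correctly learn it — that is signal, not a null. Under MCAR with
tau = 0 the pipeline's AUC and out-of-bag error sit at chance, and the
per-experiment Welch scan holds its nominal 5% type-I error.

A related, known property of out-of-bag voting: on informationless
data the aggregated OOB error lands *above* 0.5 (we measure ≈0.55 at
the pipeline scale, up to ≈0.7 in the degenerate all-constant-features
case), because each tree's out-of-bag prediction is slightly
anti-correlated with the held-out label and majority voting amplifies
the bias. Vote fractions remain centered at 0.5; no skill is invented.

## Numerical and design choices

- Split gains below 10⁻¹² count as no admissible split; nodes then
  become majority leaves. Midpoints that collapse onto a neighbor under
  floating-point rounding fall back to the lower value; a split that
  would produce an empty child becomes a leaf.
- Determinism: every stage is a pure function of its inputs and a
  single master seed. Per-tree seeds come from `numpy.SeedSequence`
  spawning keyed on (model index, tree index); negative draw *i* uses
  master_seed + i so individual draws can be re-derived; the CLI logs
  all derived seeds in `report.json`.
- Curation: keyword exclusion is case-insensitive substring matching
  over the concatenated location strings (so "reticulum" also catches
  "endoplasmic reticulum"); entries lacking an annotation score pass
  the score filter only when the minimum is 0 (absent evidence is not
  high confidence); the manual literature-review step is modeled as
  explicit inclusion/exclusion id lists.
- The "±" spread of feature counts is ambiguous between sd and MAD in
  common reporting; both are emitted.
- Score reporting for proteins that served as drawn negatives: the
  exported mean is over all k models, with an `is_training_negative`
  flag so users can filter; within those models the protein's score is
  its out-of-bag vote fraction.
- `report.json` is validated against a JSON Schema shipped with the
  package (`src/mccp/schemas/report.schema.json`) by a small structural
  validator.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full default-scale
pipeline (2000 × 45, k = 10 × 500 trees) for the signal and null
recovery checks; cross-validation in the acceptance script uses 20
folds per draw, and the shift-scan calibration uses 200 replicate null
datasets of 300 proteins × 15 experiments. Unit and property tests use
matrices of 6–600 proteins; oracle-equivalence checks (brute-force Gini
tree, exhaustive pair counting, direct Welch formulas) run on ≤ 200
instances where exhaustive enumeration is exact.

## Known limitations

- MIA is one defensible missing-value contract among several
  (surrogate splits, fractional instance weighting); results on heavily
  missing data depend on the contract.
- Balanced redraws sample the negative universe but never cover it;
  k = 10 leaves sd estimates of the score themselves noisy.
- The score threshold's false-positive calibration relies on the
  category map supplied by the user (or derived from catalogs); the
  package cannot detect annotation errors in those catalogs.
- Conditional members — proteins residing in the organelle only under
  some conditions — covary only partially with the reference and will
  score low by construction.
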