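# mccp — multiclassifier combinatorial proteomics

`mccp` predicts the protein membership of an *untargeted* organelle from
its trace — its "shadow" — in quantitative proteomics data collected for
a different cellular structure. The motivating case: mitochondrial
proteins appear as low-abundance contaminants in chromatin-enrichment
SILAC experiments, yet they rise and fall *coordinately* across
biological conditions. That covariation is a learnable signature, so an
organelle can be targeted during data analysis instead of biochemically.
The approach is aimed at compartments that cannot be purified at all
(nuclear bodies, phase-separated condensates), for which a biochemical
isolation-based proteome is out of reach.

## Method

The input is a proteins × experiments matrix **X** of log2 SILAC ratios
with abundant missing values (a protein must be quantified in at least
`min_obs` experiments — default 10 — to enter the analysis). Given a
curated set *P* of known organelle proteins detected in the matrix,
membership is scored by an ensemble of random forests:

- each forest has 500 Gini-impurity trees, 6 candidate features (`mtry`)
  per split, unlimited depth, grown on bootstrap samples;
- missing values are never imputed: each split evaluates both
  "missing → left" and "missing → right" routings and stores the better
  one (missingness incorporated in attribute), so informative dropout is
  exploited and an instance with any pattern of missingness can be scored;
- training is *balanced*: each forest uses all of *P* as positives and
  an equal-sized negative set drawn uniformly from the proteins carrying
  no organelle annotation in any supplied catalog. Because a single
  balanced draw undersamples the negative universe, the workflow is
  repeated *k* = 10 times with fresh negative draws;
- a protein's score from one forest is the fraction of trees voting
  "organelle"; the ensemble reports the mean and standard deviation over
  the k forests. Proteins used for training receive out-of-bag (or, via
  the CLI, 100-fold cross-validated) scores, so exported training scores
  are not inflated by memorization.

Accuracy is estimated by the out-of-bag error of each forest and by the
ROC AUC of cross-validated training scores. Downstream statistics
include per-experiment Welch *t* scans of organelle enrichment or
depletion, a score-cutoff false-positive report, consensus benchmarking
against independent localization catalogs, and feature-count analysis
(Mann–Whitney). A synthetic-data generator plants a covarying organelle
module in a noise matrix so the whole pipeline is testable end to end
without any external data.

## Worked example

Simulate a 500-protein matrix over 30 experiments with a planted 10%
organelle module, then run the pipeline against the generated truth
catalog:

```sh
cat > sim.yaml <<EOF
n_proteins: 500
n_experiments: 30
organelle_fraction: 0.1
missing_rate: 0.3
seed: 42
EOF
cat > run.yaml <<EOF
target_label: organelle
n_trees: 200
mtry: 6
k_classifiers: 5
cv_folds: 10
master_seed: 42
EOF
mccp simulate --config sim.yaml --out data
mccp run --config run.yaml --matrix data/matrix.tsv \
         --catalog data/truth_catalog.tsv --out results
```

which logs

```
INFO:mccp:simulated 467 proteins x 30 experiments (seed 42, 33 rows dropped)
INFO:mccp:run complete: 467 proteins, mean CV AUC 0.985, mean OOB 0.058
```

33 of 500 simulated proteins fell below the 10-observation entry filter.
The mean cross-validated AUC of 0.985 and the mean out-of-bag error of
0.058 say the five forests separate planted organelle proteins from
background nearly perfectly at this signal-to-noise. `results/`
contains `scores.tsv` (per-protein mean ± sd ensemble score with
training-set flags), `roc.tsv` (one cross-validated ROC curve per
negative draw), `shifts.tsv` (per-experiment Welch enrichment tests of
the reference group), and `report.json` (all statistics, seeds and
config echo, validated against the schema in `src/mccp/schemas/`).

The same steps run from Python via `mccp.simulate_dataset`,
`mccp.train_multiclassifier` and the functions in `mccp.evaluation`.

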