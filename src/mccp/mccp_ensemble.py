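"""The learning core: balanced-resampling random-forest ensemble (MCCP).

A single forest is a bag of missing-value-aware Gini trees (see
``_tree``): 500 trees by default, six random candidate features per
split, unlimited depth, each tree grown on a bootstrap sample of the
balanced positive/negative training rows.  A protein's score from one
forest is the fraction of trees voting the positive class.

Because the negative class ("everything not in the organelle") is far
larger than the positive reference, the workflow trains k forests
(default 10), each with the same positives but a freshly drawn balanced
negative set, and reports the mean and standard deviation of the k
scores per protein.  The out-of-bag (OOB) error of each forest is an
inbuilt unbiased estimate of its test error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tree import _grow_tree, _predict_tree
from .matrix_io import RatioMatrix
from .reference_builder import ReferenceSet, draw_negative_sets

_UNLIMITED_DEPTH = 2**31


@dataclass
class TrainingConfig:
    """Hyperparameters of the MCCP workflow.

    n_trees: trees per forest.  mtry: candidate features per split (kept
    fixed, not recomputed as sqrt(p)).  max_depth: None means unlimited.
    k_classifiers: number of balanced negative redraws / forests.
    cv_folds: folds for cross-validated training scores.  score_cutoff:
    mean-score threshold used in reporting.  min_obs: minimum feature
    count for a protein to enter the matrix.  master_seed: the single
    seed all randomness derives from.
    """

    n_trees: int = 500
    mtry: int = 6
    max_depth: int | None = None
    k_classifiers: int = 10
    cv_folds: int = 100
    score_cutoff: float = 0.69
    min_obs: int = 10
    master_seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.k_classifiers < 1:
            raise ValueError("k_classifiers must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 <= self.score_cutoff <= 1.0:
            raise ValueError("score_cutoff must be in [0, 1]")


@dataclass
class ForestModel:
    """One trained forest: flat tree arrays plus bootstrap bookkeeping."""

    trees: list[tuple]                # per tree: (feat, thr, miss_left, left, right, leaf)
    inbag: np.ndarray                 # (n_trees, n_train) bootstrap draw counts
    training_ids: list[str]           # row ids, positives first
    y: np.ndarray                     # labels aligned with training_ids
    X: np.ndarray                     # training feature rows (NaN = missing)
    seed: int
    n_features: int

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting positive for each row of X."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros(X.shape[0], dtype=np.float64)
        out = np.empty(X.shape[0], dtype=np.int64)
        for feat, thr, ml, left, right, leaf in self.trees:
            _predict_tree(feat, thr, ml, left, right, leaf, X, out)
            votes += out
        return votes / len(self.trees)


@dataclass
class EnsembleScores:
    """Aggregated per-protein scores across the k forests."""

    protein_ids: list[str]
    per_model_scores: np.ndarray      # (n_proteins, k)
    is_positive_reference: np.ndarray = None
    is_training_negative: np.ndarray = None

    def __post_init__(self):
        self.per_model_scores = np.asarray(self.per_model_scores, dtype=np.float64)
        n = len(self.protein_ids)
        if self.per_model_scores.shape[0] != n:
            raise ValueError("score rows do not match protein ids")
        if self.is_positive_reference is None:
            self.is_positive_reference = np.zeros(n, dtype=bool)
        if self.is_training_negative is None:
            self.is_training_negative = np.zeros(n, dtype=bool)

    @property
    def n_models(self) -> int:
        return self.per_model_scores.shape[1]

    @property
    def mean_score(self) -> np.ndarray:
        return self.per_model_scores.mean(axis=1)

    @property
    def sd_score(self) -> np.ndarray:
        if self.n_models == 1:
            return np.zeros(len(self.protein_ids))
        return self.per_model_scores.std(axis=1, ddof=1)

    def score_of(self, pid: str) -> float:
        return float(self.mean_score[self.protein_ids.index(pid)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "mean_score": self.mean_score,
                "sd_score": self.sd_score,
                "n_models": self.n_models,
                "is_positive_reference": self.is_positive_reference.astype(int),
                "is_training_negative": self.is_training_negative.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _tree_seeds(seed: int, n_trees: int) -> np.ndarray:
    """Independent 32-bit seeds for each tree of a forest."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_trees, dtype=np.uint32)


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig,
    seed: int,
    bootstrap: bool = True,
) -> list[tuple]:
    """Grow cfg.n_trees trees on (X, y); returns (trees, inbag)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    n = X.shape[0]
    mtry = min(cfg.mtry, X.shape[1])
    depth = cfg.max_depth if cfg.max_depth is not None else _UNLIMITED_DEPTH
    sample_idx = np.arange(n, dtype=np.int64)
    trees = []
    inbag = np.zeros((cfg.n_trees, n), dtype=np.int64)
    for t, ts in enumerate(_tree_seeds(seed, cfg.n_trees)):
        feat, thr, ml, left, right, leaf, bag = _grow_tree(
            X, y, sample_idx, mtry, depth, np.int64(ts), bootstrap
        )
        trees.append((feat, thr, ml, left, right, leaf))
        inbag[t] = bag
    return trees, inbag


def train_forest(
    m: RatioMatrix,
    pos: set[str],
    neg: set[str],
    cfg: TrainingConfig,
    seed: int,
    bootstrap: bool = True,
) -> ForestModel:
    """Train one forest on the matrix rows of pos (label 1) and neg (label 0).

    The ``bootstrap=False`` switch (each tree sees every training row)
    exists for equivalence testing against a deterministic single tree.
    """
    pos, neg = set(pos), set(neg)
    if pos & neg:
        raise ValueError("positive and negative training sets overlap")
    if not pos or not neg:
        raise ValueError("both training classes must be nonempty")
    if cfg.mtry > m.n_experiments:
        raise ValueError(
            f"mtry={cfg.mtry} exceeds {m.n_experiments} experiments"
        )
    ids = sorted(pos) + sorted(neg)
    rows = m.row_index(ids)
    X = m.values[rows]
    y = np.array([1] * len(pos) + [0] * len(neg), dtype=np.int64)
    trees, inbag = _fit_forest(X, y, cfg, seed, bootstrap=bootstrap)
    return ForestModel(
        trees=trees,
        inbag=inbag,
        training_ids=ids,
        y=y,
        X=X,
        seed=seed,
        n_features=m.n_experiments,
    )


def oob_score(model: ForestModel) -> tuple[np.ndarray, float, int]:
    """Out-of-bag vote fractions and error of a forest.

    Each training instance is classified by majority vote of only the
    trees whose bootstrap sample excluded it (ties vote negative).
    Returns (per-instance OOB positive-vote fraction, error rate,
    number of instances never out of bag — excluded from the error).
    The vote fraction is NaN for never-OOB instances.
    """
    n = len(model.training_ids)
    pos_votes = np.zeros(n)
    n_votes = np.zeros(n)
    out = np.empty(n, dtype=np.int64)
    X = np.ascontiguousarray(model.X, dtype=np.float64)
    for t, (feat, thr, ml, left, right, leaf) in enumerate(model.trees):
        oob_mask = model.inbag[t] == 0
        if not oob_mask.any():
            continue
        _predict_tree(feat, thr, ml, left, right, leaf, X, out)
        pos_votes[oob_mask] += out[oob_mask]
        n_votes[oob_mask] += 1
    covered = n_votes > 0
    frac = np.full(n, np.nan)
    frac[covered] = pos_votes[covered] / n_votes[covered]
    pred = (frac[covered] > 0.5).astype(np.int64)  # tie -> negative
    err = float(np.mean(pred != model.y[covered])) if covered.any() else np.nan
    return frac, err, int((~covered).sum())


def score_proteins(
    models: list[ForestModel],
    m: RatioMatrix,
    cv_scores: list[dict[str, float]] | None = None,
) -> EnsembleScores:
    """Score every protein of the matrix with each forest and aggregate.

    A protein's per-model score is the forest's positive vote fraction.
    When *cv_scores* is given (one dict per model mapping training ids
    to cross-validated scores), a protein used in a model's training
    receives that model's cross-validated score instead of the resubstitution
    vote.
    """
    if not models:
        raise ValueError("need at least one model")
    X = m.values
    k = len(models)
    scores = np.empty((m.n_proteins, k))
    for j, model in enumerate(models):
        if model.n_features != m.n_experiments:
            raise ValueError("model feature space does not match matrix")
        scores[:, j] = model.vote_fraction(X)
        if cv_scores is not None and cv_scores[j]:
            for pid, s in cv_scores[j].items():
                i = m.row_index([pid])[0]
                scores[i, j] = s
    return EnsembleScores(protein_ids=list(m.protein_ids), per_model_scores=scores)


@dataclass
class MulticlassifierResult:
    """Everything a k-forest MCCP run produces."""

    models: list[ForestModel]
    scores: EnsembleScores
    per_model_oob: np.ndarray
    negative_sets: list[set[str]]
    provenance: dict = field(default_factory=dict)

    @property
    def oob_mean(self) -> float:
        return float(np.mean(self.per_model_oob))

    @property
    def oob_sd(self) -> float:
        return float(np.std(self.per_model_oob, ddof=1)) if len(self.per_model_oob) > 1 else 0.0


def train_multiclassifier(
    m: RatioMatrix,
    ref: ReferenceSet,
    cfg: TrainingConfig,
    n_per_set: int | None = None,
    unbiased_training_scores: bool = True,
) -> MulticlassifierResult:
    """Run the full balanced-resampling ensemble.

    Draws cfg.k_classifiers negative sets from the reference's negative
    pool (restricted to the matrix), trains one forest per draw with the
    shared positives, and aggregates scores and OOB statistics.  Balanced
    training: n_per_set defaults to the number of detected positives.

    With ``unbiased_training_scores`` (default) a protein that served as
    training data for a model receives that model's out-of-bag vote
    fraction instead of the resubstitution vote, so exported training
    scores are not inflated by memorization.  Cross-validated scores can
    be substituted afterwards via ``score_proteins(cv_scores=...)``.
    """
    positives = ref.positives & set(m.protein_ids)
    if len(positives) < 2:
        raise ValueError(
            f"reference too small: only {len(positives)} positives detected in matrix"
        )
    if n_per_set is None:
        n_per_set = len(positives)
    pool = ref.negative_pool & set(m.protein_ids)
    excluded = set(m.protein_ids) - pool
    neg_sets = draw_negative_sets(
        m, excluded, n_per_set, cfg.k_classifiers, cfg.master_seed
    )
    forest_seeds = np.random.SeedSequence([cfg.master_seed, 0x666F7265]).generate_state(
        cfg.k_classifiers
    )
    models, oobs, oob_fracs = [], [], []
    for j in range(cfg.k_classifiers):
        model = train_forest(m, positives, neg_sets[j], cfg, int(forest_seeds[j]))
        frac, err, _ = oob_score(model)
        models.append(model)
        oobs.append(err)
        oob_fracs.append(frac)
    scores = score_proteins(models, m)
    if unbiased_training_scores:
        for j, model in enumerate(models):
            rows = m.row_index(model.training_ids)
            ok = ~np.isnan(oob_fracs[j])
            scores.per_model_scores[rows[ok], j] = oob_fracs[j][ok]
    pos_mask = np.array([p in positives for p in m.protein_ids])
    any_neg = set().union(*neg_sets)
    neg_mask = np.array([p in any_neg for p in m.protein_ids])
    scores.is_positive_reference = pos_mask
    scores.is_training_negative = neg_mask
    provenance = {
        "master_seed": cfg.master_seed,
        "k_classifiers": cfg.k_classifiers,
        "n_trees": cfg.n_trees,
        "mtry": cfg.mtry,
        "n_positives": len(positives),
        "n_per_negative_set": n_per_set,
        "negative_pool_size": len(pool),
        "forest_seeds": [int(s) for s in forest_seeds],
        "reference_provenance": ref.provenance,
    }
    return MulticlassifierResult(
        models=models,
        scores=scores,
        per_model_oob=np.array(oobs),
        negative_sets=neg_sets,
        provenance=provenance,
    )
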