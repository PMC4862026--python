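"""Performance evaluation and downstream statistics.

Covers stratified k-fold cross-validation of the training set, ROC/AUC,
the score-cutoff false-positive report, per-experiment enrichment or
depletion scans (Welch t-test of the organelle group against the rest in
each SILAC ratio column), annotation-consensus benchmarking across
several localization catalogs, and the feature-count comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .matrix_io import AnnotationCatalog, RatioMatrix
from .mccp_ensemble import EnsembleScores, TrainingConfig, _fit_forest, _predict_tree

CATEGORIES = (
    "reference_positive",
    "other_known_positive",
    "poorly_annotated",
    "clear_negative",
)


@dataclass
class RocCurve:
    """ROC curve with trapezoidal AUC (ties get half credit, i.e. the
    AUC equals the midrank Mann-Whitney statistic)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, sep="\t", index=False)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC for binary labels (1/True = positive).

    Raises ValueError when only one class is present.
    """
    y = np.asarray([1 if l in (1, True, "pos") else 0 for l in labels])
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


@dataclass
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def two_group_welch_test(a, b) -> WelchResult:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate inputs: if both groups have zero variance the test is
    undefined; equal means give t=0, p=1, differing means the p->0
    limit, both flagged degenerate.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, np.inf, 1.0, degenerate=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(t, np.inf, 0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class ShiftResult:
    """Welch test of the group against the rest in one experiment."""

    experiment_id: str
    n_group: int
    n_rest: int
    mean_diff: float      # group minus rest, log2 units
    t_stat: float
    p_value: float
    testable: bool = True


def experiment_shift_scan(m: RatioMatrix, group: set[str]) -> list[ShiftResult]:
    """Per-experiment enrichment/depletion of a protein group.

    For every experiment the group's non-missing log2 ratios are compared
    with those of all other proteins by a two-sided Welch t-test.  An
    experiment where either side has fewer than two values (or both
    sides are constant) is reported NOT testable.
    """
    if not group:
        raise ValueError("group must be nonempty")
    in_group = np.array([p in group for p in m.protein_ids])
    results = []
    for j, exp in enumerate(m.experiment_ids):
        col = m.values[:, j]
        g = col[in_group & ~np.isnan(col)]
        r = col[~in_group & ~np.isnan(col)]
        if len(g) < 2 or len(r) < 2:
            results.append(
                ShiftResult(exp, len(g), len(r), np.nan, np.nan, np.nan, testable=False)
            )
            continue
        w = two_group_welch_test(g, r)
        results.append(
            ShiftResult(
                exp,
                len(g),
                len(r),
                float(g.mean() - r.mean()),
                w.t_stat,
                w.p_value,
                testable=not w.degenerate,
            )
        )
    return results


def shift_scan_frame(results: list[ShiftResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class CutoffReport:
    """Who is selected at a score cutoff, and how wrong are we.

    fp_fraction is the share of selected proteins that are clearly not
    organelle members (well annotated, no organelle evidence) — the
    study's estimate of the false-positive rate at the cutoff.
    """

    threshold: float
    predicted_ids: set[str]
    counts: dict[str, int]
    fp_fraction: float


def cutoff_report(
    scores: EnsembleScores, threshold: float, categories: dict[str, str]
) -> CutoffReport:
    """Tabulate annotation categories among proteins scoring >= threshold.

    *categories* maps protein id to one of reference_positive,
    other_known_positive, poorly_annotated, clear_negative; selected
    proteins missing from the map count as poorly_annotated.
    """
    mean = scores.mean_score
    selected = {
        pid for pid, s in zip(scores.protein_ids, mean) if s >= threshold
    }
    counts = {c: 0 for c in CATEGORIES}
    for pid in selected:
        cat = categories.get(pid, "poorly_annotated")
        if cat not in counts:
            raise ValueError(f"unknown category {cat!r} for {pid!r}")
        counts[cat] += 1
    fp = counts["clear_negative"] / len(selected) if selected else 0.0
    return CutoffReport(
        threshold=threshold, predicted_ids=selected, counts=counts, fp_fraction=fp
    )


def cross_validate(
    m: RatioMatrix,
    pos: set[str],
    neg: set[str],
    cfg: TrainingConfig,
    seed: int,
) -> tuple[dict[str, float], RocCurve]:
    """Stratified k-fold cross-validation of one training set.

    Instances are shuffled (seeded) into cfg.cv_folds stratified folds;
    for each fold a forest is trained on the remainder and the held-out
    instances receive its positive vote fraction.  Every instance is
    scored exactly once; the ROC is computed on the pooled held-out
    scores.  Returns ({id: cv score}, RocCurve).
    """
    pos, neg = set(pos), set(neg)
    if pos & neg:
        raise ValueError("positive and negative sets overlap")
    ids = sorted(pos) + sorted(neg)
    if cfg.cv_folds > len(ids):
        raise ValueError("more folds than training instances")
    rows = m.row_index(ids)
    X = m.values[rows]
    y = np.array([1] * len(pos) + [0] * len(neg), dtype=np.int64)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed % (2**32))
    fold_seeds = np.random.SeedSequence([seed, 0xCF]).generate_state(cfg.cv_folds)
    cv = np.full(len(ids), np.nan)
    out = np.empty(X.shape[0], dtype=np.int64)
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assert len(np.unique(y[train_idx])) == 2, "fold lost a class"
        trees, _ = _fit_forest(X[train_idx], y[train_idx], cfg, int(fold_seeds[f]))
        Xt = np.ascontiguousarray(X[test_idx])
        votes = np.zeros(len(test_idx))
        outt = np.empty(len(test_idx), dtype=np.int64)
        for feat, thr, ml, left, right, leaf in trees:
            _predict_tree(feat, thr, ml, left, right, leaf, Xt, outt)
            votes += outt
        cv[test_idx] = votes / len(trees)
    assert not np.isnan(cv).any(), "an instance was never held out"
    curve = roc_auc(cv, y)
    return dict(zip(ids, cv)), curve


@dataclass
class ConsensusReport:
    """Agreement of the ensemble scores with independent catalogs.

    For each minimum agreement level a (>=1 .. >=C catalogs annotating a
    protein with the target label) and for exact full agreement, reports
    protein counts over the catalog union, counts restricted to proteins
    detected in the matrix, and the median ensemble mean score of the
    detected proteins.  venn_counts gives the count of every
    catalog-membership pattern over the union.
    """

    levels: list[int]
    total_counts: dict[int, int]
    detected_counts: dict[int, int]
    median_scores: dict[int, float]
    exact_full_total: int
    exact_full_detected: int
    exact_full_median: float
    venn_counts: dict[str, int] = field(default_factory=dict)


def consensus_agreement(
    scores: EnsembleScores,
    catalogs: list[AnnotationCatalog],
    target_label: str,
    m: RatioMatrix,
) -> ConsensusReport:
    """Benchmark scores against the consensus of several catalogs."""
    if not catalogs:
        raise ValueError("need at least one catalog")
    C = len(catalogs)
    member_sets = [cat.ids_with_label(target_label) for cat in catalogs]
    union = set().union(*member_sets)
    names = [cat.source or f"catalog_{i+1}" for i, cat in enumerate(catalogs)]
    agreement = {pid: sum(pid in s for s in member_sets) for pid in union}
    score_map = dict(zip(scores.protein_ids, scores.mean_score))
    detected = set(m.protein_ids)

    levels = list(range(1, C + 1))
    total_counts, detected_counts, median_scores = {}, {}, {}
    for a in levels:
        ids_a = {p for p, c in agreement.items() if c >= a}
        det = ids_a & detected
        total_counts[a] = len(ids_a)
        detected_counts[a] = len(det)
        vals = [score_map[p] for p in det if p in score_map]
        median_scores[a] = float(np.median(vals)) if vals else np.nan

    full = {p for p, c in agreement.items() if c == C}
    full_det = full & detected
    full_vals = [score_map[p] for p in full_det if p in score_map]

    venn: dict[str, int] = {}
    for pid in union:
        pattern = "+".join(n for n, s in zip(names, member_sets) if pid in s)
        venn[pattern] = venn.get(pattern, 0) + 1

    return ConsensusReport(
        levels=levels,
        total_counts=total_counts,
        detected_counts=detected_counts,
        median_scores=median_scores,
        exact_full_total=len(full),
        exact_full_detected=len(full_det),
        exact_full_median=float(np.median(full_vals)) if full_vals else np.nan,
        venn_counts=venn,
    )


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of a over b with half credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p for |U - mn/2| on small samples."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n1 = len(a)
    center = n1 * len(b) / 2.0
    observed = abs(_midrank_u(a, b) - center)
    hits = total = 0
    all_idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n1):
        sa = pooled[list(comb)]
        sb = pooled[list(all_idx - set(comb))]
        total += 1
        if abs(_midrank_u(sa, sb) - center) >= observed - 1e-12:
            hits += 1
    return hits / total


@dataclass
class FeatureCountComparison:
    median_a: float
    sd_a: float
    mad_a: float
    median_b: float
    sd_b: float
    mad_b: float
    p_value: float
    n_a: int
    n_b: int


def feature_count_analysis(
    m: RatioMatrix, set_a: set[str], set_b: set[str]
) -> FeatureCountComparison:
    """Compare the feature counts (non-missing cells) of two protein sets.

    Reports median and spread (both sd and median absolute deviation) per
    set and a two-sided Mann-Whitney p-value for the difference — a rank
    test, since feature counts are discrete and skewed.  Small samples
    (pooled n <= 16) get the exact permutation p of the symmetric
    statistic |U - mn/2|; larger ones the tie-corrected normal
    approximation without continuity correction, so identical sets give
    p = 1 exactly in both regimes.
    """
    counts = m.observation_counts()
    idx = {p: i for i, p in enumerate(m.protein_ids)}
    ca = np.array([counts[idx[p]] for p in sorted(set_a) if p in idx])
    cb = np.array([counts[idx[p]] for p in sorted(set_b) if p in idx])
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("a set has no proteins in the matrix")
    if np.all(np.concatenate([ca, cb]) == ca[0]):
        p_value = 1.0  # every count tied: no evidence of a difference
    elif len(ca) + len(cb) <= 16:
        p_value = _exact_mw_p(ca, cb)
    else:
        res = stats.mannwhitneyu(
            ca, cb, alternative="two-sided", use_continuity=False, method="asymptotic"
        )
        p_value = float(min(res.pvalue, 1.0))
    return FeatureCountComparison(
        median_a=float(np.median(ca)),
        sd_a=float(ca.std(ddof=1)) if len(ca) > 1 else 0.0,
        mad_a=float(np.median(np.abs(ca - np.median(ca)))),
        median_b=float(np.median(cb)),
        sd_b=float(cb.std(ddof=1)) if len(cb) > 1 else 0.0,
        mad_b=float(np.median(np.abs(cb - np.median(cb)))),
        p_value=p_value,
        n_a=len(ca),
        n_b=len(cb),
    )
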