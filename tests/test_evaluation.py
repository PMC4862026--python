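import numpy as np
import pytest

from mccp import (
    EnsembleScores,
    RatioMatrix,
    TrainingConfig,
    cross_validate,
    cutoff_report,
    consensus_agreement,
    experiment_shift_scan,
    feature_count_analysis,
    roc_auc,
    two_group_welch_test,
)
from mccp.matrix_io import AnnotationCatalog, CatalogEntry
from mccp.synthetic_data import SimulationParams, simulate_dataset

from _oracles import exact_mannwhitney_p, pair_count_auc, welch_formula
from conftest import matrix_from_arrays, separable_data


class TestRocAuc:
    def test_hand_counted_example(self):
        # pos>neg pairs: 3 of 4 -> AUC 0.75
        curve = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        curve = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding provokes ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-9
        )

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(np.linspace(0, 1, 40))
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)


class TestWelch:
    def test_identical_samples(self):
        r = two_group_welch_test([1, 2, 3], [1, 2, 3])
        assert r.t_stat == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_derived_example_matches_closed_form(self):
        a, b = [1.1, 0.9, 1.0], [0.0, 0.2, -0.2]
        r = two_group_welch_test(a, b)
        t, df, p = welch_formula(a, b)
        assert r.t_stat == pytest.approx(t, abs=1e-12)
        assert r.df == pytest.approx(df, abs=1e-12)
        assert r.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(3, 40))
        b = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(3, 40))
        r = two_group_welch_test(a, b)
        t, df, p = welch_formula(a, b)
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)
        rs = two_group_welch_test(b, a)
        assert rs.t_stat == pytest.approx(-r.t_stat, abs=1e-10)
        assert rs.p_value == pytest.approx(r.p_value, abs=1e-10)

    def test_degenerate_zero_variance(self):
        same = two_group_welch_test([1.0, 1.0], [1.0, 1.0])
        assert same.degenerate and same.p_value == 1.0 and same.t_stat == 0.0
        diff = two_group_welch_test([1.0, 1.0], [2.0, 2.0])
        assert diff.degenerate and diff.p_value == 0.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_welch_test([1.0], [1.0, 2.0])


class TestShiftScan:
    def test_planted_shift_signs_recovered(self):
        params = SimulationParams(
            n_proteins=600, n_experiments=30, organelle_fraction=0.25,
            shift_sd=1.0, noise_sd=0.3, missing_rate=0.1, seed=4,
            missing_mode="mcar", n_extra_modules=0,
        )
        m, truth = simulate_dataset(params)
        results = experiment_shift_scan(m, truth.organelle_ids())
        big = [
            (r, d) for r, d in zip(results, truth.shifts)
            if abs(d) > params.noise_sd and r.testable
        ]
        agree = sum(np.sign(r.mean_diff) == np.sign(d) for r, d in big)
        assert agree >= 0.9 * len(big)

    def test_untestable_experiment_flagged(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [0.5, 1.0], [0.7, np.nan]])
        m = matrix_from_arrays(vals)
        res = experiment_shift_scan(m, {m.protein_ids[0], m.protein_ids[1]})
        assert res[0].testable and not res[1].testable
        assert np.isnan(res[1].p_value)

    def test_empty_group_rejected(self):
        m = matrix_from_arrays(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            experiment_shift_scan(m, set())


class TestCrossValidate:
    def test_partition_and_perfect_auc_on_separable_toy(self):
        X, y = separable_data(30, 5, gap=6.0, seed=1)
        m = matrix_from_arrays(X)
        pos = {p for p, l in zip(m.protein_ids, y) if l == 1}
        neg = set(m.protein_ids) - pos
        cfg = TrainingConfig(n_trees=50, mtry=3, cv_folds=5)
        cv, curve = cross_validate(m, pos, neg, cfg, seed=0)
        assert set(cv) == pos | neg          # every instance scored exactly once
        assert curve.auc == pytest.approx(1.0)

    def test_recovers_planted_module(self, small_recovery):
        params, m, truth, ref, cfg, result = small_recovery
        cfg20 = TrainingConfig(n_trees=100, k_classifiers=1, cv_folds=8, master_seed=5)
        pos = ref.positives & set(m.protein_ids)
        cv, curve = cross_validate(m, pos, result.negative_sets[0], cfg20, seed=5)
        assert curve.auc >= 0.90

    def test_too_many_folds_rejected(self):
        X, y = separable_data(3, 3)
        m = matrix_from_arrays(X)
        pos = {p for p, l in zip(m.protein_ids, y) if l == 1}
        cfg = TrainingConfig(cv_folds=100)
        with pytest.raises(ValueError):
            cross_validate(m, pos, set(m.protein_ids) - pos, cfg, seed=0)


class TestCutoffReport:
    def test_toy_recount(self):
        ids = [f"P{i}" for i in range(10)]
        scores = EnsembleScores(ids, np.linspace(0, 0.9, 10).reshape(-1, 1))
        cats = {
            "P9": "reference_positive", "P8": "other_known_positive",
            "P7": "clear_negative", "P6": "reference_positive",
            # P5 uncovered -> poorly_annotated
        }
        rep = cutoff_report(scores, 0.5, cats)
        assert rep.predicted_ids == {"P5", "P6", "P7", "P8", "P9"}
        assert rep.counts == {
            "reference_positive": 2, "other_known_positive": 1,
            "poorly_annotated": 1, "clear_negative": 1,
        }
        assert rep.fp_fraction == pytest.approx(0.2)
        assert sum(rep.counts.values()) == len(rep.predicted_ids)

    def test_threshold_above_max_is_empty(self):
        scores = EnsembleScores(["P1"], np.array([[0.4]]))
        rep = cutoff_report(scores, 0.99, {})
        assert rep.predicted_ids == set() and rep.fp_fraction == 0.0


class TestConsensus:
    def make_catalogs(self):
        member = {
            "A": ["c1", "c2", "c3"], "B": ["c1", "c2"], "C": ["c1"],
            "D": ["c2", "c3"], "E": ["c3"], "F": ["c1", "c2", "c3"],
            "G": [], "H": ["c2"],
        }
        cats = []
        for name in ["c1", "c2", "c3"]:
            entries = {
                pid: CatalogEntry({"organelle"}, 5)
                for pid, cs in member.items() if name in cs
            }
            cats.append(AnnotationCatalog(entries=entries, source=name))
        return member, cats

    def test_toy_agreement_and_venn(self):
        member, cats = self.make_catalogs()
        ids = list("ABCDEFGH")
        m = matrix_from_arrays(np.zeros((8, 2)), prefix="")
        m = RatioMatrix(ids, ["e1", "e2"], np.zeros((8, 2)))
        scores = EnsembleScores(ids, np.linspace(0.1, 0.8, 8).reshape(-1, 1))
        rep = consensus_agreement(scores, cats, "organelle", m)
        counts = {pid: len(cs) for pid, cs in member.items()}
        for a in (1, 2, 3):
            assert rep.total_counts[a] == sum(c >= a for c in counts.values())
        assert rep.exact_full_total == 2  # A and F
        assert sum(rep.venn_counts.values()) == sum(bool(c) for c in member.values())
        assert rep.venn_counts["c1+c2+c3"] == 2
        # counts at level >= a are nonincreasing in a
        assert rep.total_counts[1] >= rep.total_counts[2] >= rep.total_counts[3]

    def test_median_over_detected_only(self):
        member, cats = self.make_catalogs()
        ids = ["A", "B"]  # only A and B detected in the matrix
        m = RatioMatrix(ids, ["e1"], np.zeros((2, 1)))
        scores = EnsembleScores(ids, np.array([[0.9], [0.3]]))
        rep = consensus_agreement(scores, cats, "organelle", m)
        assert rep.detected_counts[1] == 2
        assert rep.median_scores[1] == pytest.approx(0.6)
        assert rep.median_scores[3] == pytest.approx(0.9)  # only A has all 3

    def test_single_catalog_degenerate(self):
        _, cats = self.make_catalogs()
        m = RatioMatrix(["A"], ["e1"], np.zeros((1, 1)))
        scores = EnsembleScores(["A"], np.array([[0.5]]))
        rep = consensus_agreement(scores, cats[:1], "organelle", m)
        assert rep.levels == [1] and rep.exact_full_total == rep.total_counts[1]

    def test_no_catalog_rejected(self):
        m = RatioMatrix(["A"], ["e1"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            consensus_agreement(EnsembleScores(["A"], np.array([[0.5]])), [], "x", m)


class TestFeatureCounts:
    def make_matrix(self, counts):
        n_exp = max(counts) + 1
        vals = np.full((len(counts), n_exp), np.nan)
        for i, c in enumerate(counts):
            vals[i, :c] = 1.0
        return matrix_from_arrays(vals)

    def test_identical_sets_give_p_one(self):
        m = self.make_matrix([3, 5, 8, 2])
        s = set(m.protein_ids)
        r = feature_count_analysis(m, s, s)
        assert r.p_value == pytest.approx(1.0)
        assert r.median_a == r.median_b

    def test_known_medians_and_exact_p(self):
        m = self.make_matrix([3, 3, 4, 8, 9, 10])
        a = set(m.protein_ids[:3])
        b = set(m.protein_ids[3:])
        r = feature_count_analysis(m, a, b)
        assert r.median_a == 3 and r.median_b == 9
        assert r.p_value == pytest.approx(exact_mannwhitney_p([3, 3, 4], [8, 9, 10]))

    def test_spread_reported_as_sd_and_mad(self):
        m = self.make_matrix([2, 4, 6, 11, 13, 15])
        r = feature_count_analysis(m, set(m.protein_ids[:3]), set(m.protein_ids[3:]))
        assert r.sd_a == pytest.approx(np.std([2, 4, 6], ddof=1))
        assert r.mad_b == pytest.approx(2.0)

    def test_empty_intersection_rejected(self):
        m = self.make_matrix([3, 4])
        with pytest.raises(ValueError):
            feature_count_analysis(m, {"nope"}, set(m.protein_ids))
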