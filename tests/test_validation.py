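"""AUC/Youden oracles, performance tables, calibration, cross-validation."""

import itertools

import numpy as np
import pytest

from flaretaper.jlcm import ModelSpec
from flaretaper.prediction import RiskPrediction
from flaretaper.validation import (
    auc_roc,
    calibration,
    crossvalidate,
    patient_folds,
    performance_at_cutoff,
    youden_cutoff,
)

from conftest import exponential_params, simulate_faithful_cohort, two_class_params


def preds_from(risks, labels, patients=None):
    patients = patients or [f"p{i}" for i in range(len(risks))]
    return [
        RiskPrediction(course_id=f"c{i}", patient_id=pid, landmark=1.0,
                       horizon=13.0, risk=float(r), label=lab, at_baseline=False)
        for i, (r, lab, pid) in enumerate(zip(risks, labels, patients))
    ]


def brute_force_auc(risks, y):
    wins = 0.0
    pairs = 0
    for (r1, y1), (r0, y0) in itertools.product(zip(risks, y), repeat=2):
        if y1 == 1 and y0 == 0:
            pairs += 1
            wins += 1.0 if r1 > r0 else (0.5 if r1 == r0 else 0.0)
    return wins / pairs


def brute_force_youden(risks, y):
    best_c, best_j = None, -np.inf
    for c in sorted(set(risks)):
        pos = np.asarray(risks) >= c
        y = np.asarray(y)
        sens = (pos & (y == 1)).sum() / (y == 1).sum()
        spec = (~pos & (y == 0)).sum() / (y == 0).sum()
        if sens + spec - 1 > best_j + 1e-12:
            best_j, best_c = sens + spec - 1, c
    return best_c


class TestAuc:
    def test_perfect_separation(self):
        p = preds_from([0.9, 0.8, 0.1, 0.2], ["flare", "flare", "no-flare", "no-flare"])
        assert auc_roc(p) == 1.0

    def test_all_identical_risks(self):
        p = preds_from([0.5] * 6, ["flare"] * 3 + ["no-flare"] * 3)
        assert auc_roc(p) == 0.5

    def test_mixed_ties_match_pairwise_count(self):
        risks = [0.2, 0.2, 0.5, 0.5, 0.7, 0.1]
        labels = ["flare", "no-flare", "flare", "no-flare", "flare", "no-flare"]
        p = preds_from(risks, labels)
        y = [1 if l == "flare" else 0 for l in labels]
        assert auc_roc(p) == pytest.approx(brute_force_auc(risks, y), abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 200))
            risks = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            labels = ["flare" if v else "no-flare" for v in y]
            assert auc_roc(preds_from(risks, labels)) == pytest.approx(
                brute_force_auc(risks, y), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="undefined AUC"):
            auc_roc(preds_from([0.5, 0.6], ["flare", "flare"]))

    def test_indeterminate_excluded(self):
        p = preds_from([0.9, 0.1, 0.99], ["flare", "no-flare", "indeterminate"])
        assert auc_roc(p) == 1.0


class TestYouden:
    def test_perfect_separation_returns_lowest_positive_risk(self):
        p = preds_from([0.9, 0.7, 0.2, 0.1], ["flare", "flare", "no-flare", "no-flare"])
        assert youden_cutoff(p) == 0.7

    def test_all_identical_risks(self):
        p = preds_from([0.4] * 4, ["flare", "no-flare", "flare", "no-flare"])
        assert youden_cutoff(p) == 0.4

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(4, 200))
            risks = np.round(rng.random(n), 1)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            labels = ["flare" if v else "no-flare" for v in y]
            assert youden_cutoff(preds_from(risks, labels)) == pytest.approx(
                brute_force_youden(list(risks), list(y)))


class TestPerformanceTable:
    def test_two_by_two_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5 at cutoff 0.5
        risks = [0.9, 0.8, 0.7, 0.6] + [0.2, 0.3, 0.1, 0.2, 0.4, 0.3]
        labels = (["flare"] * 3 + ["no-flare"]) + (["flare"] + ["no-flare"] * 5)
        t = performance_at_cutoff(preds_from(risks, labels), 0.5, n_boot=50, seed=0)
        assert t.sensitivity == pytest.approx(0.75)
        assert t.specificity == pytest.approx(5 / 6)
        assert t.ppv == pytest.approx(0.75)
        assert t.npv == pytest.approx(5 / 6)
        assert t.accuracy == pytest.approx(0.8)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lo, hi = t.ci[name]
            assert lo - 1e-12 <= getattr(t, name) <= hi + 1e-12
            assert 0.0 <= lo <= hi <= 1.0

    def test_cutoff_below_all_risks(self):
        t = performance_at_cutoff(
            preds_from([0.3, 0.5], ["flare", "no-flare"]), 0.0, n_boot=10, seed=0)
        assert t.sensitivity == 1.0 and t.specificity == 0.0

    def test_empty_positive_set_flags_ppv(self):
        t = performance_at_cutoff(
            preds_from([0.1, 0.2], ["flare", "no-flare"]), 0.9, n_boot=10, seed=0)
        assert not t.ppv_defined and np.isnan(t.ppv)

    def test_degenerate_cohort_zero_width_ci(self):
        # one patient owning every prediction: bootstrap resamples are copies
        p = preds_from([0.9, 0.1], ["flare", "no-flare"], patients=["p0", "p0"])
        t = performance_at_cutoff(p, 0.5, n_boot=30, seed=0)
        assert t.ci["sensitivity"] == (1.0, 1.0)
        assert t.ci["accuracy"] == (1.0, 1.0)


class TestCalibration:
    def test_eight_predictions_make_groups_of_two(self):
        risks = [0.05, 0.1, 0.2, 0.25, 0.4, 0.45, 0.7, 0.8]
        labels = ["no-flare"] * 4 + ["flare"] * 4
        groups = calibration(preds_from(risks, labels))
        assert list(groups.n) == [2, 2, 2, 2]
        assert groups.n.sum() == 8
        assert np.all(np.diff(groups.bounds) >= 0)
        assert np.all(np.diff(groups.mean_predicted) > 0)

    def test_all_equal_degenerate_group_flagged(self):
        groups = calibration(preds_from([0.3] * 6, ["flare", "no-flare"] * 3))
        assert groups.degenerate and len(groups.n) == 1

    def test_too_few_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration(preds_from([0.2, 0.4], ["flare", "no-flare"]))

    def test_generating_model_predictions_sit_near_diagonal(self):
        """Risks computed from the generating model itself are calibrated:
        per-quartile observed flare frequency tracks mean predicted risk."""
        from flaretaper.generate import (GeneratorConfig,
                                         generate_development_cohort, true_risk)
        from flaretaper.prediction import RiskPrediction, landmark_predictions
        from conftest import make_results
        cfg = GeneratorConfig(n_courses=700)
        courses, _ = generate_development_cohort(cfg, seed=33)
        params = cfg.truth()
        fitted = make_results(params, ModelSpec(2, 2))
        preds = landmark_predictions(courses, fitted)
        oracle = [
            RiskPrediction(course_id=p.course_id, patient_id=p.patient_id,
                           landmark=p.landmark, horizon=p.horizon,
                           risk=true_risk(params, c, p.landmark, p.horizon),
                           label=p.label, at_baseline=p.at_baseline)
            for p, c in ((p, next(c for c in courses if c.course_id == p.course_id))
                         for p in preds)
        ]
        groups = calibration(oracle)
        assert len(oracle) > 2000
        assert np.all(np.abs(groups.mean_predicted - groups.observed_frequency) < 0.1)


class TestCrossValidation:
    def test_folds_partition_and_keep_patients_together(self):
        p = exponential_params()
        courses = simulate_faithful_cohort(p, n=30, seed=2, taper_half=False)
        # give some patients two courses
        for i in (1, 3, 5):
            courses[i].patient_id = courses[i - 1].patient_id
        folds = patient_folds(courses, k=5, seed=0)
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(30))
        fold_of = {}
        for j, f in enumerate(folds):
            for i in f:
                fold_of[courses[i].patient_id] = fold_of.get(courses[i].patient_id, j)
                assert fold_of[courses[i].patient_id] == j
    def test_each_course_predicted_exactly_once(self):
        p = exponential_params(rho=0.008)
        courses = simulate_faithful_cohort(p, n=40, seed=6, taper_half=False)
        preds = crossvalidate(courses, ModelSpec(1, 1), k=4, seed=0, n_starts=1,
                              maxiter=150)
        seen = {p.course_id for p in preds}
        expected = {c.course_id for c in courses
                    if c.first_flare_time is None or c.first_flare_time > 0}
        # every course contributes landmarks from exactly one (held-out) fold
        assert seen == expected

    def test_strong_signal_reaches_high_auc(self):
        """Well-separated classes with extreme hazard contrast: pooled
        out-of-fold AUC exceeds 0.9."""
        p = two_class_params()
        p.pi = np.array([0.5, 0.5])
        p.beta = np.array([[1.8, 0.0, 0.0], [3.1, 0.0, 0.0]])
        p.B = np.diag([0.01, 1e-8])
        p.sigma2 = 0.04
        p.kappa = 1.0
        p.rho = 0.0008
        p.gamma1 = np.array([0.0, 3.5])   # class-2 hazard ~ e^3.5 by year 1
        p.gamma2 = np.array([0.0, 0.0])
        p.beta_surv = np.zeros(8)
        p.delta = 0.0
        courses = simulate_faithful_cohort(p, n=120, seed=8, taper_half=False)
        auc = auc_roc(crossvalidate(courses, ModelSpec(2, 1), k=3, seed=0,
                                    n_starts=2, maxiter=300))
        assert auc > 0.9
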