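import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import shelladc as sa
from shelladc.decision_inference import HIGH, LOW
from shelladc.errors import (
    InsufficientDataError,
    ParameterError,
    SeparationError,
    ValidationError,
)


def brute_force_auc(scores, labels, rule=HIGH):
    """Concordant-pair counting with tie weight 1/2 over all pos x neg pairs."""
    s = -np.asarray(scores, float) if rule == LOW else np.asarray(scores, float)
    labels = np.asarray(labels)
    pos, neg = s[labels == 1], s[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_toy_auc_five_sixths(self):
        scores = [3, 5, 1, 2, 4]
        labels = [1, 1, 0, 0, 0]
        assert sa.auc_empirical(scores, labels) == pytest.approx(5 / 6)
        assert brute_force_auc(scores, labels) == pytest.approx(5 / 6)

    def test_perfect_separation_auc_one(self):
        assert sa.auc_empirical([10, 9, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_sweep_matches_pair_counting_with_ties(self, rng):
        for n in (10, 47, 200):
            scores = rng.integers(0, 12, size=n).astype(float)  # heavy ties
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            for rule in (HIGH, LOW):
                assert sa.auc_empirical(scores, labels, rule) == pytest.approx(
                    brute_force_auc(scores, labels, rule), abs=1e-12
                )

    def test_sweep_matches_sklearn_oracle(self, rng):
        scores = rng.random(80)
        labels = (rng.random(80) < 0.4).astype(int)
        assert sa.auc_empirical(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_endpoints_and_monotonicity(self, rng):
        curve = sa.roc(rng.random(60), (rng.random(60) < 0.5).astype(int))
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)

    def test_low_direction_classifies_leq_cutoff(self):
        curve = sa.roc([0.4, 0.5, 0.7, 0.8], [1, 1, 0, 0], LOW)
        pt = sa.youden_cutoff(curve)
        assert pt.sensitivity == 1.0 and pt.specificity == 1.0
        assert 0.5 <= pt.cutoff < 0.7

    def test_null_permutation_auc_near_half(self, rng):
        aucs = []
        for _ in range(30):
            scores = rng.random(200)
            labels = rng.permutation([1] * 80 + [0] * 120)
            aucs.append(sa.auc_empirical(scores, labels))
        dev = np.abs(np.array(aucs) - 0.5)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)
        assert np.mean(dev < 0.1) >= 0.9

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            sa.roc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison_p_one(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.4).astype(int)
        a = sa.roc(scores, labels)
        assert sa.delong_compare(a, a) == pytest.approx(1.0)

    def test_monotone_transform_p_one(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.4).astype(int)
        a = sa.roc(scores, labels)
        b = sa.roc(np.exp(3 * scores), labels)
        assert sa.delong_compare(a, b) == pytest.approx(1.0)

    def test_variance_agrees_with_bootstrap(self, rng):
        scores = np.concatenate([rng.standard_normal(30),
                                 rng.standard_normal(30) + 1.0])
        labels = np.array([0] * 30 + [1] * 30)
        res = sa.delong_auc_inference(sa.roc(scores, labels))
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, 60, 60)
            if labels[idx].min() == labels[idx].max():
                continue
            boot.append(sa.auc_empirical(scores[idx], labels[idx]))
        assert res.variance == pytest.approx(np.var(boot, ddof=1), rel=0.25)

    def test_all_tied_scores_degenerate(self):
        curve = sa.roc([1.0] * 20, [0] * 10 + [1] * 10)
        res = sa.delong_auc_inference(curve)
        assert res.auc == 0.5
        assert res.p_vs_half == 1.0
        assert res.degenerate

    def test_separated_curve_degenerate_flag(self):
        curve = sa.roc([1, 2, 3, 8, 9, 10.0], [0, 0, 0, 1, 1, 1])
        res = sa.delong_auc_inference(curve)
        assert res.degenerate and res.ci_low == res.ci_high == 1.0
        assert res.p_vs_half < 1e-300

    def test_subject_mismatch_rejected(self, rng):
        a = sa.roc(rng.random(20), [0, 1] * 10)
        b = sa.roc(rng.random(20), [1, 0] * 10)
        with pytest.raises(ValidationError):
            sa.delong_compare(a, b)


class TestOperatingPoints:
    def test_youden_perfect_separation(self):
        curve = sa.roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], HIGH)
        pt = sa.youden_cutoff(curve)
        assert pt.sensitivity + pt.specificity - 1 == pytest.approx(1.0)

    def test_youden_matches_exhaustive_search(self, rng):
        scores = rng.random(68)
        labels = np.array([1] * 27 + [0] * 41)
        curve = sa.roc(scores, labels, LOW)
        pt = sa.youden_cutoff(curve)
        best_j = -np.inf
        for c in np.concatenate([[-np.inf], np.sort(scores), [np.inf]]):
            pred = scores <= c
            sens = (pred & (labels == 1)).sum() / 27
            spec = (~pred & (labels == 0)).sum() / 41
            best_j = max(best_j, sens + spec - 1)
        assert pt.sensitivity + pt.specificity - 1 == pytest.approx(best_j,
                                                                    abs=1e-12)

    def test_flat_scores_degenerate_youden(self):
        curve = sa.roc([2.0] * 10, [0] * 5 + [1] * 5)
        pt = sa.youden_cutoff(curve)
        assert pt.degenerate
        assert pt.sensitivity + pt.specificity - 1 == pytest.approx(0.0)

    def test_fixed_specificity_picks_smallest_achievable_above_target(self, rng):
        # distinct scores with 41 negatives: every specificity k/41 achievable;
        # target 0.80 must select 33/41 = 0.805, not 32/41 = 0.780
        scores = rng.permutation(np.arange(68, dtype=float))
        labels = np.array([1] * 27 + [0] * 41)
        curve = sa.roc(scores, labels, LOW)
        pt = sa.operating_point_at(curve, "fixed_specificity", 0.80)
        assert pt.specificity == pytest.approx(33 / 41)

    def test_fixed_target_reports_achieved_point_on_curve(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.45).astype(int)
        curve = sa.roc(scores, labels, LOW)
        for strategy, target in [("fixed_specificity", 0.8),
                                 ("fixed_specificity", 0.9),
                                 ("fixed_sensitivity", 0.8)]:
            pt = sa.operating_point_at(curve, strategy, target)
            pairs = set(zip(curve.sensitivity, curve.specificity))
            assert (pt.sensitivity, pt.specificity) in pairs

    def test_separation_toy_sensitivity_one_at_any_spec(self):
        curve = sa.roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], HIGH)
        pt = sa.operating_point_at(curve, "fixed_specificity", 0.99)
        assert pt.sensitivity == 1.0

    def test_unreachable_target_rejected(self, rng):
        curve = sa.roc(rng.random(20), [0, 1] * 10)
        with pytest.raises(ParameterError):
            sa.operating_point_at(curve, "fixed_specificity", 1.2)


class TestConfusionReconstruction:
    @pytest.mark.parametrize(
        "sens,spec,tp,tn,ppv,npv,acc",
        [
            (0.667, 0.780, 18, 32, 0.667, 0.780, 0.735),  # Youden cutoff row
            (0.593, 0.805, 16, 33, 0.667, 0.750, 0.721),  # spec ~80%
            (0.519, 0.854, 14, 35, 0.700, 0.729, 0.721),  # spec ~85%
            (0.333, 0.951, 9, 39, 0.818, 0.684, 0.706),   # spec ~90-95%
            (0.815, 0.366, 22, 15, 0.458, 0.750, 0.544),  # sens ~80%
        ],
    )
    def test_reconstruction_from_printed_rates(self, sens, spec, tp, tn,
                                               ppv, npv, acc):
        counts, p, n, a = sa.confusion_from_rates(sens, spec, 27, 41)
        assert (counts.tp, counts.tn) == (tp, tn)
        assert counts.tp + counts.fn == 27
        assert counts.tn + counts.fp == 41
        assert p == pytest.approx(ppv, abs=5e-4)
        assert n == pytest.approx(npv, abs=5e-4)
        assert a == pytest.approx(acc, abs=5e-4)

    def test_perfect_rates(self):
        _, ppv, npv, acc = sa.confusion_from_rates(1.0, 1.0, 10, 10)
        assert (ppv, npv, acc) == (1.0, 1.0, 1.0)

    def test_degenerate_rates_missing(self):
        _, ppv, npv, acc = sa.confusion_from_rates(0.0, 1.0, 5, 5)
        assert np.isnan(ppv)
        assert npv == 0.5 and acc == 0.5


class TestFrozenThreshold:
    def test_extreme_cutoff(self):
        pt = sa.apply_frozen_threshold([2.0, 3, 4, 5], [1, 0, 1, 0],
                                       cutoff=1.0, rule_direction=LOW)
        assert pt.sensitivity == 0.0 and pt.specificity == 1.0

    def test_constructed_cohort_hits_half_sensitivity(self):
        """10+10 cohort built so 5/10 positives and 8/10 negatives fall on
        the correct side of a frozen 0.552 cutoff (low predicts positive)."""
        pos = [0.50] * 5 + [0.60] * 5
        neg = [0.60] * 8 + [0.50] * 2
        pt = sa.apply_frozen_threshold(pos + neg, [1] * 10 + [0] * 10,
                                       cutoff=0.552, rule_direction=LOW)
        assert pt.sensitivity == pytest.approx(0.50)
        assert pt.specificity == pytest.approx(0.80)

    def test_missing_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            sa.apply_frozen_threshold([1.0, 2.0], [0, 0], 1.5, LOW)


class TestLogistic:
    def test_null_predictor_odds_ratio_near_one(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            y = (rng.random(500) < 0.4).astype(float)
            X = pd.DataFrame({"x": rng.standard_normal(500)})
            res = sa.fit_logistic(y, X)
            assert 0.8 < res.effects[0].odds_ratio < 1.25

    def test_rescaling_invariance(self, rng):
        y = (rng.random(120) < 0.4).astype(float)
        x = rng.random(120)
        r1 = sa.fit_logistic(y, pd.DataFrame({"x": x}), {"x": "per_0.1"})
        r2 = sa.fit_logistic(y, pd.DataFrame({"x": x * 10}), {"x": "identity"})
        assert r1.effects[0].odds_ratio == pytest.approx(
            r2.effects[0].odds_ratio, abs=1e-8
        )
        assert r1.model_auc == pytest.approx(r2.model_auc, abs=1e-12)

    def test_perfect_separation_detected(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        X = pd.DataFrame({"x": np.arange(20.0)})
        with pytest.raises(SeparationError):
            sa.fit_logistic(y, X)

    def test_volume_doubling_scale(self, rng):
        y = (rng.random(200) < 0.4).astype(float)
        vol = np.exp(rng.standard_normal(200) + 8)
        r1 = sa.fit_logistic(y, pd.DataFrame({"v": vol}), {"v": "per_doubling"})
        r2 = sa.fit_logistic(y, pd.DataFrame({"v": np.log2(vol)}),
                             {"v": "identity"})
        assert r1.effects[0].odds_ratio == pytest.approx(
            r2.effects[0].odds_ratio, abs=1e-8
        )


class TestValidateInternal:
    def test_fixed_marker_no_overfit_identity(self, rng):
        scores, labels = sa.simulate_marker(27, 41, 0.725, rng)
        res = sa.validate_internal(scores, labels, HIGH,
                                   repeats=50, n_boot=400, seed=7)
        assert res.cv_mean_auc == pytest.approx(res.apparent_auc, abs=0.02)
        assert abs(res.optimism) < 0.01

    def test_same_seed_bit_identical(self, rng):
        scores, labels = sa.simulate_marker(20, 30, 0.7, rng)
        a = sa.validate_internal(scores, labels, HIGH, repeats=20,
                                 n_boot=100, seed=3)
        b = sa.validate_internal(scores, labels, HIGH, repeats=20,
                                 n_boot=100, seed=3)
        assert a == b

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ParameterError):
            sa.validate_internal([1.0, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0],
                                 folds=5)
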