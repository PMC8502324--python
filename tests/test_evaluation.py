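"""Diagnostic indexes, Wald intervals, and the published-table identities."""

import math

import numpy as np
import pytest

from losnet.evaluation import (
    auc_binary,
    confusion,
    evaluate,
    incorrect_classification,
    likelihood_ratios,
    roc_auc,
    round_half_away,
    wald_interval,
)

# Validation-set results of the department study, one column per model:
# (sensitivity %, specificity %, occurrence, n) -> printed
# (incorrect %, FPR %, FNR %, LR+, LR-, AUC).  Frozen as a regression table;
# three printed entries carry a one-ulp rounding artifact (see tolerance).
TABLE_COLUMNS = [
    # outcome, unit, sens, spec, occ, n, incorrect, fpr, fnr, lr+, lr-, auc
    ("long", "department", 69.34, 48.59, 1148, 2819, 42.96, 51.41, 30.66, 1.35, 0.63, 0.59),
    ("long", "internal medicine", 68.98, 40.46, 187, 449, 47.66, 59.54, 31.02, 1.16, 0.77, 0.55),
    ("long", "cardiology", 77.50, 53.17, 80, 411, 42.09, 46.83, 22.50, 1.66, 0.42, 0.65),
    ("long", "emergency medicine", 63.51, 54.22, 148, 373, 42.09, 45.78, 36.49, 1.39, 0.67, 0.59),
    ("long", "geriatrics", 70.86, 52.07, 175, 296, 36.82, 47.93, 29.14, 1.48, 0.56, 0.61),
    ("long", "respiratory diseases", 62.07, 54.84, 116, 240, 41.67, 45.16, 37.93, 1.37, 0.69, 0.58),
    ("long", "neurology", 70.45, 49.31, 88, 232, 42.67, 50.69, 29.55, 1.39, 0.60, 0.60),
    ("long", "oncology", 67.21, 57.14, 61, 166, 39.16, 42.86, 32.79, 1.57, 0.57, 0.62),
    ("outlier", "department", 62.73, 51.72, 110, 2819, 47.85, 48.28, 37.27, 1.30, 0.72, 0.57),
    ("outlier", "internal medicine", 73.68, 52.44, 19, 449, 46.67, 47.56, 26.32, 1.55, 0.50, 0.63),
    ("outlier", "cardiology", 71.43, 81.68, 7, 411, 18.49, 18.32, 28.57, 3.90, 0.35, 0.77),
    ("outlier", "emergency medicine", 77.78, 61.41, 18, 373, 37.80, 38.59, 22.22, 2.02, 0.36, 0.70),
    ("outlier", "geriatrics", 77.78, 58.27, 18, 296, 40.54, 41.73, 22.22, 1.86, 0.38, 0.68),
    ("outlier", "respiratory diseases", 66.67, 66.67, 6, 240, 33.33, 33.33, 33.33, 2.00, 0.50, 0.67),
    ("outlier", "neurology", 85.71, 54.67, 7, 232, 44.40, 45.33, 14.29, 1.89, 0.26, 0.70),
    ("outlier", "oncology", 75.00, 64.81, 4, 166, 34.94, 35.19, 25.00, 2.13, 0.39, 0.70),
]


class TestConfusion:
    def test_perfect_agreement(self):
        assert confusion([1, 0, 1], [1, 0, 1]) == (2, 0, 1, 0)

    def test_total_disagreement(self):
        y = np.array([1, 0, 1, 0])
        tp, fp, tn, fn = confusion(y, 1 - y)
        assert tp == 0 and tn == 0

    def test_matches_loop_oracle(self, rng):
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):   # element-wise oracle
            if t and p: tp += 1
            elif not t and p: fp += 1
            elif not t and not p: tn += 1
            else: fn += 1
        assert confusion(y_true, y_pred) == (tp, fp, tn, fn)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])


class TestIndexFormulas:
    def test_uninformative_test_has_unit_ratios(self):
        assert likelihood_ratios(0.5, 0.5) == (1.0, 1.0)

    def test_perfect_specificity_flags_infinity(self):
        lr_pos, _ = likelihood_ratios(0.9, 1.0)
        assert lr_pos == math.inf

    def test_zero_specificity_leaves_lr_neg_undefined(self):
        _, lr_neg = likelihood_ratios(0.9, 0.0)
        assert math.isnan(lr_neg)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratios(1.2, 0.5)

    def test_perfect_classifier_has_zero_incorrect(self):
        assert incorrect_classification(1.0, 1.0, 30, 100) == 0.0

    def test_wald_degenerate_proportion(self):
        se, lo, hi = wald_interval(0.0, 50)
        assert (se, lo, hi) == (0.0, 0.0, 0.0)

    def test_auc_binary_is_three_point_trapezoid(self, rng):
        # the (sens+spec)/2 identity equals the trapezoidal area of the
        # degenerate ROC {(0,0), (fpr, sens), (1,1)}
        for _ in range(20):
            sens, spec = rng.random(2)
            fpr = 1 - spec
            xs, ys = [0, fpr, 1], [0, sens, 1]
            trapezoid = sum((xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2
                            for i in range(2))
            assert auc_binary(sens, spec) == pytest.approx(trapezoid, abs=1e-12)

    def test_lr_sign_relations(self, rng):
        # LR+ > 1 iff sens + spec > 1 iff LR- < 1
        for _ in range(50):
            sens, spec = rng.uniform(0.01, 0.99, 2)
            lr_pos, lr_neg = likelihood_ratios(sens, spec)
            informative = sens + spec > 1
            assert (lr_pos > 1) == informative
            assert (lr_neg < 1) == informative


class TestPublishedTableIdentities:
    @pytest.mark.parametrize(
        "outcome,unit,sens,spec,occ,n,inc,fpr,fnr,lr_pos,lr_neg,auc",
        TABLE_COLUMNS,
        ids=[f"{o}-{u}" for o, u, *_ in TABLE_COLUMNS])
    def test_printed_indexes_reproduce(self, outcome, unit, sens, spec, occ, n,
                                       inc, fpr, fnr, lr_pos, lr_neg, auc):
        s, p = sens / 100, spec / 100
        # one unit in the last printed digit absorbs the table's own rounding
        assert round_half_away(100 * incorrect_classification(s, p, occ, n), 2) \
            == pytest.approx(inc, abs=0.011)
        assert round_half_away(100 * (1 - p), 2) == pytest.approx(fpr, abs=0.011)
        assert round_half_away(100 * (1 - s), 2) == pytest.approx(fnr, abs=0.011)
        got_pos, got_neg = likelihood_ratios(s, p)
        assert round_half_away(got_pos, 2) == pytest.approx(lr_pos, abs=0.011)
        assert round_half_away(got_neg, 2) == pytest.approx(lr_neg, abs=0.011)
        assert round_half_away(auc_binary(s, p), 2) == pytest.approx(auc, abs=0.011)

    def test_department_long_column_exact(self):
        # headline column reproduces exactly at printed precision
        s, p, occ, n = 0.6934, 0.4859, 1148, 2819
        assert round_half_away(100 * incorrect_classification(s, p, occ, n), 2) == 42.96
        lr_pos, lr_neg = likelihood_ratios(s, p)
        assert round_half_away(lr_pos, 2) == 1.35
        assert round_half_away(lr_neg, 2) == 0.63
        assert round_half_away(auc_binary(s, p), 2) == 0.59
        se, lo, hi = wald_interval(s, occ)
        assert round_half_away(se, 3) == 0.014
        assert round_half_away(lo, 3) == 0.666
        assert round_half_away(hi, 2) == 0.72


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([1, 0, 1, 0], [1, 0, 1, 0])
        assert rep.sensitivity == rep.specificity == 1.0
        assert rep.incorrect_classification == 0.0
        assert rep.auc_binary == 1.0

    def test_constant_positive_predictor(self):
        rep = evaluate([1, 0, 1, 0], [1, 1, 1, 1])
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.lr_pos == 1.0

    def test_matches_brute_force_oracle(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        rep = evaluate(y_true, y_pred)
        # independent loop recomputation of every field
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        n, occ = len(y_true), tp + fn
        sens, spec = tp / occ, tn / (tn + fp)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
        assert rep.occurrence == occ
        assert rep.sensitivity == pytest.approx(sens)
        assert rep.specificity == pytest.approx(spec)
        assert rep.fpr == pytest.approx(1 - spec)
        assert rep.fnr == pytest.approx(1 - sens)
        assert rep.incorrect_classification == pytest.approx((fp + fn) / n)
        assert rep.lr_pos == pytest.approx(sens / (1 - spec))
        assert rep.lr_neg == pytest.approx((1 - sens) / spec)
        assert rep.auc_binary == pytest.approx((sens + spec) / 2)
        assert rep.sens_se == pytest.approx(math.sqrt(sens * (1 - sens) / occ))
        assert rep.spec_se == pytest.approx(math.sqrt(spec * (1 - spec) / (tn + fp)))

    def test_incorrect_equals_misclassified_fraction(self, rng):
        # identity: weighted-rate form == (fp+fn)/n exactly
        y_true = rng.integers(0, 2, 150)
        y_pred = rng.integers(0, 2, 150)
        rep = evaluate(y_true, y_pred)
        assert rep.incorrect_classification == pytest.approx(
            (rep.fp + rep.fn) / rep.n, abs=1e-15)

    def test_score_based_roc_auc(self, rng):
        y = rng.integers(0, 2, 80)
        scores = y + rng.normal(0, 0.5, 80)   # informative scores
        rep = evaluate(y, (scores >= 0.5).astype(int), scores=scores)
        assert 0.5 < rep.auc_roc <= 1.0
        # separable scores give AUC exactly 1
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
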