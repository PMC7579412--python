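import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from ddgbench.core import BenchmarkSet, PredictionRecord
from ddgbench.metrics import (
    JoinError,
    classification_counts,
    classification_table,
    evaluate,
    filtered_pearson,
    mcc,
    mcc_binary_stabilizing,
    pearson,
    predictive_index,
)
from ddgbench.taxonomy import CategoryLabel


def pi_brute_force(exp, pred):
    """All-pairs reference implementation of the Predictive Index."""
    num = den = 0.0
    for i, j in itertools.combinations(range(len(exp)), 2):
        de, dp = exp[j] - exp[i], pred[j] - pred[i]
        w = abs(de)
        if dp == 0 or de == 0:
            c = 0.0
        elif (de > 0) == (dp > 0):
            c = 1.0
        else:
            c = -1.0
        num += w * c
        den += w
    return num / den if den else float("nan")


def mcc_formula(conf):
    """Direct confusion-matrix formula evaluation (independent of mcc())."""
    conf = np.asarray(conf, float)
    s, c = conf.sum(), np.trace(conf)
    t, p = conf.sum(axis=1), conf.sum(axis=0)
    denom = math.sqrt((s * s - (p * p).sum()) * (s * s - (t * t).sum()))
    return (c * s - (p * t).sum()) / denom


class TestPearson:
    def test_perfect_and_inverted(self):
        x = [0.0, 1.0, 2.0, 4.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        exp, pred = np.array([0.0, 1, 2, 4]), np.array([1.0, 0, 3, 5])
        cov = np.mean((exp - exp.mean()) * (pred - pred.mean()))
        r = cov / (exp.std() * pred.std())
        assert pearson(exp, pred) == pytest.approx(r)

    def test_undefined_cases(self):
        assert math.isnan(pearson([1, 2], [1, 2]))          # n < 3
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))    # zero variance


class TestFilteredPearson:
    def test_equals_unfiltered_on_clean_linear_data(self):
        x = list(range(10))
        assert filtered_pearson(x, x) == pytest.approx(1.0)

    def test_single_gross_outlier_removed(self):
        exp = list(range(10)) + [5.0]
        pred = list(range(10)) + [50.0]
        assert pearson(exp, pred) < 0.9
        assert filtered_pearson(exp, pred, drop_fraction=0.10) == pytest.approx(1.0)

    def test_improves_on_adversarial_outlier(self):
        rng = np.random.default_rng(0)
        exp = rng.normal(size=30)
        pred = exp.copy()
        pred[17] += 40.0
        assert filtered_pearson(exp, pred) >= pearson(exp, pred)


class TestPredictiveIndex:
    def test_rank_identical_and_inverted(self):
        exp = [0.0, 1.0, 3.0]
        assert predictive_index(exp, [0.1, 0.4, 0.5]) == pytest.approx(1.0)
        assert predictive_index(exp, [-v for v in exp]) == pytest.approx(-1.0)

    def test_enumerated_example(self):
        # pairs: weights 1, 3, 2 with signs +, +, − → (1+3−2)/6 = 1/3
        assert predictive_index([0, 1, 3], [0, 2, 1]) == pytest.approx(1 / 3)

    def test_all_equal_experiment_undefined(self):
        assert math.isnan(predictive_index([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_brute_force_oracle(self, exp, data):
        pred = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False),
                     min_size=len(exp), max_size=len(exp))
        )
        got = predictive_index(exp, pred)
        want = pi_brute_force(exp, pred)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestMcc:
    def test_perfect_agreement(self):
        y = [0, 1, 2, 0, 1, 2]
        assert mcc(y, y) == pytest.approx(1.0)

    def test_hand_built_confusion_matrix(self):
        conf = np.array([[10, 2, 1], [3, 8, 2], [0, 1, 6]])
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [i] * conf[i, j]
                y_pred += [j] * conf[i, j]
        assert mcc(y_true, y_pred) == pytest.approx(mcc_formula(conf))

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(5)
        for _ in range(20):
            y_true = rng.integers(0, 3, size=40)
            y_pred = rng.integers(0, 3, size=40)
            assert mcc(y_true, y_pred) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [
            mcc(rng.integers(0, 3, size=600), rng.integers(0, 3, size=600))
            for _ in range(30)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_two_class_restriction_equals_binary_formula(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, size=50)
        y_pred = rng.integers(0, 2, size=50)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        classic = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc(y_true, y_pred, n_classes=2) == pytest.approx(classic)

    def test_degenerate_marginals_undefined_not_zero(self):
        assert math.isnan(mcc([0, 0, 0], [0, 1, 2]))

    def test_binary_stabilizing_mode(self):
        # stabilizing(2) vs not: classes 0 and 1 merge
        assert mcc_binary_stabilizing([2, 0, 2, 1], [2, 1, 2, 0]) == pytest.approx(1.0)


class TestInvariances:
    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_joint_permutation_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        exp = rng.normal(size=15)
        pred = exp + rng.normal(scale=0.5, size=15)
        perm = rng.permutation(15)
        assert pearson(exp[perm], pred[perm]) == pytest.approx(pearson(exp, pred))
        assert predictive_index(exp[perm], pred[perm]) == pytest.approx(
            predictive_index(exp, pred)
        )
        # positive affine rescale of predictions
        assert pearson(exp, 2.5 * pred + 1.0) == pytest.approx(pearson(exp, pred))
        assert predictive_index(exp, 2.5 * pred + 1.0) == pytest.approx(
            predictive_index(exp, pred)
        )

    def test_noise_attenuation_recovery(self):
        """pred = exp + ε recovers r ≈ σ_exp/√(σ_exp²+σ²) at n = 2000."""
        rng = np.random.default_rng(12)
        n, sigma_exp, sigma = 2000, 1.3, 1.3
        exp = rng.normal(scale=sigma_exp, size=n)
        pred = exp + rng.normal(scale=sigma, size=n)
        r = pearson(exp, pred)
        rho = sigma_exp / math.sqrt(sigma_exp**2 + sigma**2)
        se = (1 - rho**2) / math.sqrt(n - 3)  # Fisher-approx standard error
        assert abs(r - rho) < 3 * se


def _benchmark(n=8):
    recs = [
        make_record(wt="D", mut="K", pos=str(i + 1), ddg=float(v))
        for i, v in enumerate([-2.0, -1.5, -0.5, 0.0, 0.5, 1.0, 1.5, 2.5][:n])
    ]
    return BenchmarkSet.from_records(recs)


class TestClassificationTable:
    def test_perfect_predictions(self):
        bench = _benchmark()
        preds = {r.record_id: r.ddg_exp for r in bench.records}
        table = classification_table(bench, preds)
        for row in table.values():
            assert row["same_class_pct"] == 100.0
            assert row["off_by_one_pct"] == 0.0 and row["off_by_two_pct"] == 0.0

    def test_known_error_mix(self):
        # errors {0, 0, 1, 2} → 50 / 25 / 25
        counts = classification_counts([-2.0, 0.0, 1.5, -2.0], [-2.0, 0.0, 0.2, 2.0])
        assert counts.tolist() == [2, 1, 1]
        pct = 100 * counts / counts.sum()
        assert pct.tolist() == [50.0, 25.0, 25.0]

    def test_percentages_partition(self):
        bench = _benchmark()
        rng = np.random.default_rng(0)
        preds = {r.record_id: float(rng.normal()) for r in bench.records}
        for row in classification_table(bench, preds).values():
            assert row["same_class_pct"] + row["off_by_one_pct"] + row["off_by_two_pct"] \
                == pytest.approx(100.0)

    def test_unmatched_ids_raise_join_error(self):
        bench = _benchmark()
        with pytest.raises(JoinError):
            classification_table(bench, {})


class TestEvaluate:
    def test_single_replicate_sd_zero(self):
        bench = _benchmark()
        preds = [PredictionRecord(r.record_id, r.ddg_exp + 0.1) for r in bench.records]
        report = evaluate(bench, preds)
        for row in report.summary.sd.values():
            assert row.pearson_r == 0.0 and row.pct_same_class == 0.0

    def test_identical_replicates_mean_equals_each(self):
        bench = _benchmark()
        preds = []
        for rep in (1, 2, 3):
            preds += [
                PredictionRecord(r.record_id, 0.9 * r.ddg_exp, replicate=rep)
                for r in bench.records
            ]
        report = evaluate(bench, preds)
        one = report.rows[1][CategoryLabel.EVERYTHING]
        mean = report.summary.mean[CategoryLabel.EVERYTHING]
        assert mean.pearson_r == pytest.approx(one.pearson_r)
        assert report.summary.sd[CategoryLabel.EVERYTHING].pearson_r == pytest.approx(0.0)

    def test_replicate_mean_sd_arithmetic_oracle(self):
        bench = _benchmark()
        rng = np.random.default_rng(4)
        by_rep = {
            rep: {r.record_id: r.ddg_exp + float(rng.normal(scale=0.8))
                  for r in bench.records}
            for rep in (1, 2, 3)
        }
        report = evaluate(bench, by_rep)
        per_rep = [report.rows[rep][CategoryLabel.EVERYTHING].pearson_r for rep in (1, 2, 3)]
        assert report.summary.mean[CategoryLabel.EVERYTHING].pearson_r == \
            pytest.approx(np.mean(per_rep))
        assert report.summary.sd[CategoryLabel.EVERYTHING].pearson_r == \
            pytest.approx(np.std(per_rep, ddof=1))

    def test_scale_applied_before_classification(self):
        bench = _benchmark()
        # predictions in "2× units": rescaling by 0.5 makes them perfect
        preds = [PredictionRecord(r.record_id, 2.0 * r.ddg_exp) for r in bench.records]
        report = evaluate(bench, preds, scale=(0.5, 0.0))
        assert report.mean_egregious == 0
        row = report.summary.mean[CategoryLabel.EVERYTHING]
        assert row.pct_same_class == pytest.approx(100.0)

    def test_global_error_counts(self):
        bench = _benchmark()
        preds = {r.record_id: -r.ddg_exp for r in bench.records}
        report = evaluate(bench, {1: preds})
        exp = [r.ddg_exp for r in bench.records]
        manual = classification_counts(exp, [-v for v in exp])
        assert report.egregious_errors[1] == manual[2]
        assert report.off_by_one_errors[1] == manual[1]
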