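"""Detectors, severity regressors, cross-validation and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from pdmotion import (
    DegenerateLabelsError,
    FeatureTable,
    ParameterError,
    SubjectLabels,
    confusion_metrics,
    cross_validate,
    group_ttest,
    pearson_r,
    train_detector,
    train_severity_regressor,
)
from pdmotion.models import TREMOR_FEATURE_COLUMNS


def _cluster_table(n_per_class=20, separation=6.0, seed=0) -> FeatureTable:
    """Two well-separated Gaussian clusters in the tremor feature space."""
    rng = np.random.default_rng(seed)
    neg = rng.normal(0.0, 1.0, size=(n_per_class, 6))
    pos = rng.normal(separation, 1.0, size=(n_per_class, 6))
    features = pd.DataFrame(np.vstack([neg, pos]), columns=TREMOR_FEATURE_COLUMNS)
    labels = pd.DataFrame({"tremor_present": [False] * n_per_class + [True] * n_per_class})
    return FeatureTable(features=features, labels=labels)


def _regression_table(n=40, noise=0.0, n_noise_features=0, seed=1) -> FeatureTable:
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    y = 2.0 * x1 + 1.0 + noise * rng.normal(size=n)
    cols = {"tremor_avg_acc": x1}
    for j in range(n_noise_features):
        cols[f"noise_{j}"] = rng.normal(size=n)
    return FeatureTable(
        features=pd.DataFrame(cols),
        labels=pd.DataFrame({"hoehn_yahr": y}),
    )


class TestDetector:
    def test_separable_clusters_classified_perfectly(self):
        table = _cluster_table()
        model = train_detector(table, "tremor_present")
        pred = model.predict(table.feature_matrix(TREMOR_FEATURE_COLUMNS))
        y = table.target("tremor_present")
        assert (pred[y]).all() and (~pred[~y]).all()

    def test_single_class_labels_rejected(self):
        table = _cluster_table()
        table.labels["tremor_present"] = True
        with pytest.raises(DegenerateLabelsError):
            train_detector(table, "tremor_present")


class TestSeverityRegressor:
    def test_noiseless_linear_target_recovered(self):
        """y = 2*x + 1 with vanishing penalty recovers the slope.

        Oracle: plain Lasso at alpha -> 0 equals ordinary least squares.
        """
        table = _regression_table()
        x = table.feature_matrix()
        y = table.target("hoehn_yahr")
        ols_like = Lasso(alpha=1e-8, max_iter=100_000).fit(x, y)
        assert ols_like.coef_[0] == pytest.approx(2.0, abs=1e-3)
        assert ols_like.intercept_ == pytest.approx(1.0, abs=1e-3)
        model = train_severity_regressor(table, "hoehn_yahr", seed=0)
        assert np.allclose(model.predict(x), y, atol=0.05)

    def test_constant_target_rejected(self):
        table = _regression_table()
        table.labels["hoehn_yahr"] = 3.0
        with pytest.raises(DegenerateLabelsError):
            train_severity_regressor(table, "hoehn_yahr")

    def test_irrelevant_features_shrink_to_exact_zero(self):
        """Moderate L1 penalty zeroes pure-noise columns while the true
        predictor survives (soft-thresholding sparsity)."""
        table = _regression_table(n=60, n_noise_features=4, seed=3)
        x = table.feature_matrix()
        y = table.target("hoehn_yahr")
        fit = Lasso(alpha=0.1, max_iter=100_000).fit(x, y)
        assert fit.coef_[0] > 1.0
        assert np.all(fit.coef_[1:] == 0.0)

    def test_soft_threshold_oracle_on_orthonormal_design(self):
        """On a design with X'X = nI the Lasso solution is the
        soft-thresholded OLS estimate: sign(b)*max(|b|-alpha, 0)."""
        rng = np.random.default_rng(7)
        n, p = 16, 4
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        x = q * np.sqrt(n)
        beta = np.array([2.0, -1.0, 0.4, 0.05])
        y = x @ beta
        for alpha in (0.01, 0.1, 0.5, 1.0):
            b_ols = x.T @ y / n
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - alpha, 0.0)
            fit = Lasso(alpha=alpha, fit_intercept=False, max_iter=100_000).fit(x, y)
            np.testing.assert_allclose(fit.coef_, expected, atol=1e-6)

    def test_active_set_monotone_in_penalty(self):
        """On orthonormal designs the active set at a larger penalty is a
        subset of the active set at a smaller penalty."""
        rng = np.random.default_rng(8)
        n, p = 16, 6
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        x = q * np.sqrt(n)
        y = x @ rng.normal(size=p)
        previous = None
        for alpha in (1.0, 0.5, 0.2, 0.05, 0.01):
            active = set(np.flatnonzero(
                Lasso(alpha=alpha, fit_intercept=False, max_iter=100_000)
                .fit(x, y).coef_
            ))
            if previous is not None:
                assert previous <= active
            previous = active


class TestCrossValidate:
    def test_forty_subjects_make_five_disjoint_folds_of_eight(self):
        table = _cluster_table(n_per_class=20)
        report = cross_validate(table, "tremor_present", k=5, seed=11)
        folds = report.fold_assignment
        sizes = [int((folds == f).sum()) for f in range(5)]
        assert sizes == [8, 8, 8, 8, 8]
        assert len(np.unique(folds)) == 5  # every row validated exactly once

    def test_same_seed_reproduces_partition_and_metrics(self):
        table = _cluster_table(seed=4)
        r1 = cross_validate(table, "tremor_present", seed=5)
        r2 = cross_validate(table, "tremor_present", seed=5)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        assert r1.to_dict() == r2.to_dict()

    def test_perfect_signal_scores_one(self):
        """A feature identical to the label acts as a perfect oracle."""
        rng = np.random.default_rng(6)
        y = np.array([False, True] * 20)
        features = pd.DataFrame(
            np.column_stack([y.astype(float)] + [rng.normal(size=40)] * 5),
            columns=TREMOR_FEATURE_COLUMNS,
        )
        table = FeatureTable(features=features,
                             labels=pd.DataFrame({"tremor_present": y}))
        report = cross_validate(table, "tremor_present", seed=0)
        assert report.sensitivity == report.specificity == report.accuracy == 1.0

    def test_stratification_error_when_class_too_small(self):
        table = _cluster_table(n_per_class=20)
        table.labels.loc[3:, "tremor_present"] = True  # 3 negatives < k
        with pytest.raises(ParameterError):
            cross_validate(table, "tremor_present", k=5, seed=0)

    def test_regression_predictions_clipped_to_stage_range(self):
        table = _regression_table(n=40, noise=0.1, seed=9)
        table.labels["hoehn_yahr"] = np.clip(
            np.round(2.5 + 2 * table.features["tremor_avg_acc"]), 1, 5
        )
        report = cross_validate(table, "hoehn_yahr", seed=2)
        assert report.predictions.min() >= 1.0
        assert report.predictions.max() <= 5.0
        assert report.pearson_r > 0.8

    def test_no_leakage_between_validation_labels_and_predictions(self):
        """Permuting a fold's labels cannot change that fold's predictions
        (they were never seen in training), but must change its score."""
        table = _cluster_table(n_per_class=20, separation=2.0, seed=12)
        folds = np.tile(np.arange(5), 8)
        base = cross_validate(table, "tremor_present", seed=0, folds=folds)
        permuted = table.labels.copy()
        idx = np.flatnonzero(folds == 0)
        permuted.loc[idx, "tremor_present"] = (
            ~permuted.loc[idx, "tremor_present"].astype(bool)
        )
        other = cross_validate(
            FeatureTable(features=table.features, labels=permuted),
            "tremor_present", seed=0, folds=folds,
        )
        np.testing.assert_array_equal(
            base.predictions[idx], other.predictions[idx]
        )
        assert base.accuracy != other.accuracy


class TestEvaluationStatistics:
    def test_confusion_arithmetic(self):
        sens, spec, acc = confusion_metrics(7, 0, 10, 3)
        assert (sens, spec, acc) == (0.7, 1.0, 0.85)

    def test_empty_class_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics(0, 0, 10, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_matches_per_sample_counting(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=50).astype(bool)
        pred = rng.integers(0, 2, size=50).astype(bool)
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        tn = int(np.sum(~pred & ~truth))
        fn = int(np.sum(~pred & truth))
        sens, spec, acc = confusion_metrics(tp, fp, tn, fn)
        # brute-force loop oracle
        hits_pos = sum(1 for p, t in zip(pred, truth) if t and p)
        hits_neg = sum(1 for p, t in zip(pred, truth) if not t and not p)
        assert sens == pytest.approx(hits_pos / truth.sum())
        assert spec == pytest.approx(hits_neg / (~truth).sum())
        assert acc == pytest.approx((hits_pos + hits_neg) / 50)

    def test_pearson_extremes_and_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        truth = np.array([2.0, 2.0, 4.0, 5.0])
        cov = np.mean((pred - pred.mean()) * (truth - truth.mean()))
        expected = cov / (pred.std() * truth.std())
        assert pearson_r(pred, truth) == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_vector_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_welch_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = group_ttest(a, a)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_welch_extreme_separation(self):
        rng = np.random.default_rng(3)
        _, p = group_ttest(rng.normal(0, 0.01, 10), rng.normal(100, 0.01, 10))
        assert p < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_welch_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 12)
        t, p = group_ttest(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        from scipy.stats import t as t_dist

        p_oracle = 2 * t_dist.sf(abs(t_oracle), df)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_group_too_small_rejected(self):
        with pytest.raises(ParameterError):
            group_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestSubjectLabels:
    def test_derived_booleans(self):
        lab = SubjectLabels(tremor_updrs=2, gait_updrs=1, hoehn_yahr=2)
        assert lab.tremor_present and not lab.gait_difficulty
        lab = SubjectLabels(tremor_updrs=0, gait_updrs=2, hoehn_yahr=3)
        assert not lab.tremor_present and lab.gait_difficulty

    @pytest.mark.parametrize("kwargs", [
        {"tremor_updrs": 5, "gait_updrs": 0, "hoehn_yahr": 1},
        {"tremor_updrs": 0, "gait_updrs": -1, "hoehn_yahr": 1},
        {"tremor_updrs": 0, "gait_updrs": 0, "hoehn_yahr": 0},
    ])
    def test_out_of_range_scores_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SubjectLabels(**kwargs)
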