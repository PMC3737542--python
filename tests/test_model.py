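import numpy as np
import pytest

from mirsite import (
    DesignSpec,
    build_design,
    classify,
    cross_validate_10fold,
    fit_balanced_ensemble,
    fit_logistic,
    inter_dataset_validate,
    predict,
    roc_curve,
    top_fraction_tpr,
    youden_j,
)
from mirsite.model import auc_of, evaluate
from mirsite.synth import generate_feature_table


def design_of(df, covs, interactions="all"):
    spec = DesignSpec(list(covs), interactions)
    X, y, _ = build_design(df, spec, fit=True)
    return X, y, spec


class TestBuildDesign:
    def test_column_counts(self):
        df = generate_feature_table(50, 50, [0, 0, 0, 0], seed=1)
        for k in (2, 3, 4):
            X, _, _ = design_of(df, [f"x{i+1}" for i in range(k)])
            assert X.shape[1] == k + k * (k - 1) // 2

    def test_standardization_on_training_rows(self):
        df = generate_feature_table(200, 200, [0.5, -0.5], seed=2)
        df["x1"] = df["x1"] * 7 + 3
        X, _, spec = design_of(df, ["x1", "x2"])
        assert abs(X[:, 0].mean()) < 1e-9
        assert X[:, 0].std() == pytest.approx(1.0, abs=1e-9)
        # interaction column is the product of the standardized mains
        assert np.allclose(X[:, 2], X[:, 0] * X[:, 1])

    def test_missing_rows_dropped(self, caplog):
        df = generate_feature_table(20, 20, [0.0], seed=3)
        df.loc[df.index[:5], "x1"] = np.nan
        with caplog.at_level("INFO"):
            X, y, kept = build_design(df, DesignSpec(["x1"], None), fit=True)
        assert kept.sum() == 35 and len(X) == 35


class TestFitLogistic:
    def test_null_data_near_zero(self):
        df = generate_feature_table(1000, 1000, [0.0, 0.0], seed=4)
        X, y, _ = design_of(df, ["x1", "x2"], interactions=None)
        w = fit_logistic(X, y)
        se = np.sqrt(4 / len(y))       # asymptotic SE for balanced p=0.5
        assert abs(w[0]) < 3 * se
        assert np.all(np.abs(w[1:]) < 3 * se)

    def test_coefficient_recovery(self):
        df = generate_feature_table(5000, 5000, [1.0, -0.5], seed=5)
        X, y, _ = design_of(df, ["x1", "x2"], interactions=None)
        w = fit_logistic(X, y)
        assert w[1] == pytest.approx(1.0, abs=0.1)
        assert w[2] == pytest.approx(-0.5, abs=0.1)

    def test_row_duplication_invariance(self):
        df = generate_feature_table(200, 200, [0.8], seed=6)
        X, y, _ = design_of(df, ["x1"], interactions=None)
        w1 = fit_logistic(X, y)
        w2 = fit_logistic(np.vstack([X, X]), np.r_[y, y])
        assert np.allclose(w1, w2, atol=1e-4)

    def test_agrees_with_independent_glm_fit(self):
        # statsmodels maximizes the same likelihood by IRLS; at ridge ~ 0
        # the two routes must meet
        import statsmodels.api as sm

        df = generate_feature_table(800, 800, [0.7, -0.3], seed=19)
        X, y, _ = design_of(df, ["x1", "x2"], interactions=None)
        ours = fit_logistic(X, y, ridge=1e-10)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert np.allclose(ours, ref, atol=1e-5)

    def test_separable_data_stays_finite(self):
        X = np.r_[np.full((20, 1), -1.0), np.full((20, 1), 1.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        w = fit_logistic(X, y, ridge=1e-6)
        assert np.all(np.isfinite(w))


class TestBalancedEnsemble:
    def test_equal_sizes_degenerate_subsampling(self):
        df = generate_feature_table(100, 100, [1.0], seed=7)
        X, y, spec = design_of(df, ["x1"], interactions=None)
        ens = fit_balanced_ensemble(X[y == 1], X[y == 0], k=5, seed=1, spec=spec)
        for member in ens.coefficients[1:]:
            assert np.allclose(member, ens.coefficients[0], atol=1e-6)

    def test_same_seed_identical(self):
        df = generate_feature_table(100, 400, [1.0], seed=8)
        X, y, spec = design_of(df, ["x1"], interactions=None)
        a = fit_balanced_ensemble(X[y == 1], X[y == 0], k=5, seed=3, spec=spec)
        b = fit_balanced_ensemble(X[y == 1], X[y == 0], k=5, seed=3, spec=spec)
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_member_spread_shrinks_with_positives(self):
        spreads = []
        for n_pos, seed in ((200, 9), (2000, 10)):
            df = generate_feature_table(n_pos, 4 * n_pos, [1.0, -0.5], seed=seed)
            X, y, spec = design_of(df, ["x1", "x2"], interactions=None)
            ens = fit_balanced_ensemble(X[y == 1], X[y == 0], k=10, seed=1, spec=spec)
            spreads.append(ens.coefficients[:, 1].std())
        assert spreads[1] < spreads[0]

    def test_too_few_positives_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="too few"):
            fit_balanced_ensemble(X[:5], X[5:], k=3, seed=0)

    def test_swapped_roles_flagged(self, caplog):
        rng = np.random.default_rng(1)
        with caplog.at_level("WARNING"):
            fit_balanced_ensemble(
                rng.normal(size=(50, 1)), rng.normal(size=(20, 1)), k=2, seed=0
            )
        assert "larger" in caplog.text


class TestPredictAndClassify:
    def test_zero_model_predicts_half(self):
        ens = fit_balanced_ensemble(
            np.zeros((20, 2)), np.zeros((20, 2)), k=3, seed=0
        )
        ens.coefficients[:] = 0.0
        assert np.allclose(predict(ens, np.zeros((4, 2))), 0.5)

    def test_prediction_is_member_mean_and_order_invariant(self):
        ens = fit_balanced_ensemble(
            np.random.default_rng(2).normal(size=(20, 1)) + 2,
            np.random.default_rng(3).normal(size=(20, 1)) - 2,
            k=4, seed=1,
        )
        X = np.array([[0.3], [-1.2]])
        from scipy.special import expit
        manual = expit(
            np.hstack([np.ones((2, 1)), X]) @ ens.coefficients.T
        ).mean(axis=1)
        assert np.allclose(predict(ens, X), manual)
        ens.coefficients = ens.coefficients[::-1].copy()
        assert np.allclose(predict(ens, X), manual)

    def test_threshold_boundary_inclusive(self):
        assert classify(np.array([0.5, 0.49]), 0.5).tolist() == [True, False]
        # lowering q never flips a positive to negative
        probs = np.random.default_rng(4).random(50)
        hi = classify(probs, 0.6)
        lo = classify(probs, 0.3)
        assert np.all(lo | ~hi)


class TestRocAndRanking:
    def test_perfect_separation_passes_through_corner(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0], bool)
        fpr, tpr, thr = roc_curve(probs, labels)
        assert any(f == 0 and t == 1 for f, t in zip(fpr, tpr))
        assert fpr[0] == tpr[0] == 0 and fpr[-1] == tpr[-1] == 1
        rep = evaluate(probs, labels, q=0.5)
        assert rep.j_at_q == pytest.approx(1.0)    # TPR=1, FPR=0 at q=0.5

    def test_null_scores_have_half_auc(self):
        rng = np.random.default_rng(11)
        probs = rng.random(10000)
        labels = rng.random(10000) < 0.5
        fpr, tpr, _ = roc_curve(probs, labels)
        assert auc_of(fpr, tpr) == pytest.approx(0.5, abs=0.02)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(12)
        fpr, tpr, _ = roc_curve(rng.random(200), rng.random(200) < 0.3)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [True, True])

    def test_youden_identities(self):
        assert youden_j(0.8, 0.3) == pytest.approx(0.5)
        assert youden_j(1.0, 0.0) == 1.0
        assert youden_j(0.4, 0.4) == 0.0

    def test_top_fraction_examples(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert top_fraction_tpr(probs, labels, 0.5) == 1.0
        assert top_fraction_tpr(probs, [1, 1, 1, 1], 0.25) == 1.0
        assert top_fraction_tpr(probs, labels, 1.0) == 0.5


class TestValidationProtocols:
    def test_cv_deterministic(self):
        df = generate_feature_table(150, 450, [1.0, -0.5], seed=13)
        spec = DesignSpec(["x1", "x2"], "all")
        a = cross_validate_10fold(df, spec, seed=5)
        b = cross_validate_10fold(df, spec, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_cv_separates_strong_signal(self):
        df = generate_feature_table(400, 1200, [3.0, -2.0], seed=14)
        spec = DesignSpec(["x1", "x2"], "all")
        rep = cross_validate_10fold(df, spec, seed=6)
        assert rep.max_j >= 0.6
        assert rep.auc >= 0.85

    def test_interaction_model_beats_linear_on_interaction_data(self):
        df = generate_feature_table(
            1500, 1500, [0.0, 0.0], interaction_coeffs={(0, 1): 1.2}, seed=15
        )
        lin = cross_validate_10fold(df, DesignSpec(["x1", "x2"], None), seed=7)
        non = cross_validate_10fold(df, DesignSpec(["x1", "x2"], "all"), seed=7)
        assert non.max_j > lin.max_j

    def test_inter_dataset_identity_and_null(self):
        df = generate_feature_table(300, 900, [2.0], seed=16)
        spec = DesignSpec(["x1"], None)
        same = inter_dataset_validate(df, df, spec, seed=8)
        shuffled = df.copy()
        shuffled["ip_label"] = (
            np.random.default_rng(17).permutation(shuffled["ip_label"].to_numpy())
        )
        null = inter_dataset_validate(df, shuffled, spec, seed=8)
        assert same.max_j > 0.5
        assert abs(null.max_j) < 0.15

    def test_missing_covariate_reported(self):
        df = generate_feature_table(50, 50, [1.0], seed=18)
        test_df = df.drop(columns=["x1"])
        with pytest.raises(ValueError, match="x1"):
            inter_dataset_validate(df, test_df, DesignSpec(["x1"], None))
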