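"""Balancing, feature selection, regression fits, threshold scan, experiment."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_auc, brute_confusion, brute_ranksum_p
from tiscall.model import (
    NoSignificantFeaturesError,
    TrainedModel,
    TrainingConfig,
    auc_score,
    balance,
    confidence_class,
    fit,
    rank_sum_pvalues,
    run_experiment,
    select_features,
    threshold_scan,
)


def _labels(n_pos, n_neg):
    return pd.Series([1] * n_pos + [0] * n_neg,
                     index=[f"s{i}" for i in range(n_pos + n_neg)])


class TestBalance:
    def test_undersamples_majority(self):
        y = _labels(10, 50)
        idx = balance(y, np.random.default_rng(0))
        sub = y.loc[idx]
        assert (sub == 1).sum() == 10
        assert (sub == 0).sum() == 10
        # minority untouched
        assert set(y.index[y == 1]) <= set(idx)

    def test_already_balanced_identity(self):
        y = _labels(10, 10)
        assert list(balance(y, np.random.default_rng(0))) == list(y.index)

    def test_seed_reproducibility(self):
        y = _labels(10, 200)
        a = list(balance(y, np.random.default_rng(42)))
        b = list(balance(y, np.random.default_rng(42)))
        assert a == b
        different = sum(
            list(balance(y, np.random.default_rng(s))) != a for s in range(100)
        )
        assert different > 90  # distinct seeds give distinct draws

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            balance(_labels(0, 5), np.random.default_rng(0))


class TestRankSum:
    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            {f"f{j}": rng.normal(size=12) + (j % 2) for j in range(4)}
        )
        y = pd.Series([1] * 6 + [0] * 6)
        ours = rank_sum_pvalues(X, y)
        for col in X.columns:
            a = X[col][y == 1].to_numpy()
            b = X[col][y == 0].to_numpy()
            assert ours[col] == pytest.approx(brute_ranksum_p(a, b), abs=1e-12)

    def test_identical_distribution_not_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        X = pd.DataFrame({"flat": np.concatenate([x[:100], x[:100]])})
        y = pd.Series([1] * 100 + [0] * 100)
        assert rank_sum_pvalues(X, y)["flat"] > 0.9


class TestSelection:
    def _toy(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series([1] * n + [0] * n)
        signal = np.concatenate([rng.normal(3, 1, n), rng.normal(0, 1, n)])
        X = pd.DataFrame(
            {
                "utr_length": signal,
                "kozak_context": signal * 2 + rng.normal(0, 0.01, 2 * n),
                "utr_frac_A": rng.normal(size=2 * n),
                "kmer:pos:-3:A": signal + rng.normal(0, 0.3, 2 * n),
                "kmer:up:AUG": rng.normal(size=2 * n),
                "constant": 1.0,
            }
        )
        return X, y

    def test_constant_and_null_features_dropped(self):
        X, y = self._toy()
        report = select_features(X, y, TrainingConfig(), n_features_total=1252)
        assert "constant" not in report.kept
        assert "utr_frac_A" not in report.kept
        reasons = dict(zip(report.dropped["feature"], report.dropped["reason"]))
        assert reasons.get("constant") == "constant"

    def test_correlated_pair_keeps_smaller_p(self):
        X, y = self._toy()
        report = select_features(X, y, TrainingConfig(), n_features_total=1252)
        # utr_length and kozak_context are near-perfectly correlated:
        # exactly one survives, the one with the smaller p-value
        kept = {"utr_length", "kozak_context"} & set(report.kept)
        assert len(kept) == 1
        winner = kept.pop()
        loser = ({"utr_length", "kozak_context"} - {winner}).pop()
        assert report.pvalues[winner] <= report.pvalues[loser]
        assert loser in set(report.dropped["feature"])

    def test_kept_set_pairwise_uncorrelated_and_significant(self):
        X, y = self._toy()
        config = TrainingConfig()
        report = select_features(X, y, config, n_features_total=1252)
        corr = X[report.kept].corr().to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert (np.abs(off) < config.r_max).all()
        assert (report.pvalues[report.kept] < config.alpha / 1252).all()

    def test_bonferroni_uses_total_feature_count(self):
        X, y = self._toy()
        report = select_features(X, y, TrainingConfig(), n_features_total=1252)
        assert report.bonferroni_alpha == pytest.approx(0.01 / 1252)

    def test_no_signal_raises(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"noise": rng.normal(size=40)})
        y = pd.Series([1] * 20 + [0] * 20)
        with pytest.raises(NoSignificantFeaturesError):
            select_features(X, y, TrainingConfig(), n_features_total=1252)

    def test_top_kmer_cap(self):
        rng = np.random.default_rng(4)
        n = 60
        y = pd.Series([1] * n + [0] * n)
        signal = np.concatenate([np.full(n, 1.0), np.zeros(n)])
        cols = {
            f"kmer:pos:{i}:A": signal + rng.normal(0, 1e-3, 2 * n)
            for i in range(-60, 0)
        }
        X = pd.DataFrame(cols)
        config = TrainingConfig(top_kmers=50)
        report = select_features(X, y, config, n_features_total=1252)
        assert len(report.candidate_pool) <= 50


class TestFit:
    def test_exact_linear_relation_recovered(self):
        x = np.linspace(-2, 2, 50)
        X = pd.DataFrame({"f": x})
        y = pd.Series(0.3 * x + 0.2)
        model = fit(X, y, TrainingConfig())
        # transform back to the raw-feature scale
        slope = model.params["coef"][0] / model.norm_sd[0]
        intercept = (
            model.params["intercept"]
            - model.params["coef"][0] * model.norm_mean[0] / model.norm_sd[0]
        )
        assert slope == pytest.approx(0.3, abs=1e-9)
        assert intercept == pytest.approx(0.2, abs=1e-9)

    def test_null_fit_gives_class_mean(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"f": rng.normal(size=2000)})
        y = pd.Series(rng.permutation([1.0] * 1000 + [0.0] * 1000))
        model = fit(X, y, TrainingConfig())
        assert model.params["coef"][0] == pytest.approx(0.0, abs=0.05)
        assert model.params["intercept"] == pytest.approx(0.5, abs=0.05)

    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(6)
        n, sigma = 2000, 0.1
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        w = np.array([0.4, -0.25, 0.1])
        y = pd.Series(X.to_numpy() @ w + 0.3 + rng.normal(0, sigma, n))
        model = fit(X, y, TrainingConfig())
        Z = (X.to_numpy() - model.norm_mean) / model.norm_sd
        A = np.column_stack([Z, np.ones(n)])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(A.T @ A)))
        w_z = w * model.norm_sd  # weights on the z-scored scale
        for j in range(3):
            assert abs(model.params["coef"][j] - w_z[j]) < 3 * se[j]

    def test_clamping_of_predictions(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 2.0]})
        model = TrainedModel(
            feature_names=["f"], norm_mean=np.zeros(1), norm_sd=np.ones(1),
            model_kind="linear", params={"coef": np.array([1.0]),
                                         "intercept": -0.45},
        )
        raw = model.predict_raw(X)
        conf = model.predict_confidence(X)
        assert raw == pytest.approx([-0.45, 0.55, 1.55])
        assert conf == pytest.approx([0.0, 0.55, 1.0])

    def test_missing_feature_is_named(self):
        model = TrainedModel(
            feature_names=["f"], norm_mean=np.zeros(1), norm_sd=np.ones(1),
            model_kind="linear", params={"coef": np.array([1.0]), "intercept": 0.0},
        )
        with pytest.raises(KeyError, match="f"):
            model.predict_confidence(pd.DataFrame({"g": [1.0]}))

    def test_svr_grid_search_and_manual_kernel_predicts(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        y = pd.Series((X["a"] * 0.5 + 0.5 > 0.4).astype(float))
        config = TrainingConfig(model_kind="svr_rbf", cv_folds=5)
        model = fit(X, y, config, seed=7)
        assert model.params["C"] in config.C_grid
        assert model.params["epsilon"] in config.epsilon_grid
        # manual kernel prediction agrees with sklearn on the training data
        from sklearn.svm import SVR

        Z = (X.to_numpy() - model.norm_mean) / model.norm_sd
        ref = SVR(kernel="rbf", C=model.params["C"],
                  epsilon=model.params["epsilon"], gamma=model.params["gamma"])
        ref.fit(Z, y.to_numpy())
        assert model.predict_raw(X) == pytest.approx(ref.predict(Z), abs=1e-8)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = pd.Series(rng.random(50))
        model = fit(X, y, TrainingConfig())
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TrainedModel.from_json(path)
        assert back.predict_confidence(X) == pytest.approx(
            model.predict_confidence(X), abs=1e-12
        )


class TestThresholdScan:
    def test_extreme_thresholds(self):
        conf = np.array([0.2, 0.8, 0.4, 0.9])
        y = np.array([0, 1, 0, 1])
        table, _ = threshold_scan(conf, y)
        at0 = table.iloc[0]
        assert at0["sensitivity"] == 1.0 and at0["specificity"] == 0.0

    def test_perfect_separation(self):
        conf = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        table, best_t = threshold_scan(conf, y)
        assert table["accuracy"].max() == 1.0
        assert auc_score(conf, y) == 1.0
        assert 0.2 < best_t <= 0.8

    def test_twenty_point_toy_matches_brute_force(self):
        rng = np.random.default_rng(9)
        conf = np.round(rng.random(20), 3)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 1, 0  # both classes present
        table, _ = threshold_scan(conf, y)
        for _, row in table.iterrows():
            tp, fp, tn, fn = brute_confusion(conf, y, row["threshold"])
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (tp, fp, tn, fn)
            assert row["accuracy"] == pytest.approx((tp + tn) / 20)
            if tp + fn:
                assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert row["precision"] == pytest.approx(tp / (tp + fp))
        assert auc_score(conf, y) == pytest.approx(brute_auc(conf, y))

    def test_auc_matches_sklearn_and_pairwise_count(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        conf = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        assert auc_score(conf, y) == pytest.approx(roc_auc_score(y, conf))
        assert auc_score(conf, y) == pytest.approx(brute_auc(conf, y))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        conf = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        base = auc_score(conf, y)
        assert auc_score(conf**3, y) == pytest.approx(base)
        assert auc_score(1 - np.exp(-3 * conf), y) == pytest.approx(base)

    def test_single_class_auc_is_missing(self):
        assert np.isnan(auc_score(np.array([0.1, 0.9]), np.array([1, 1])))

    def test_grid_has_101_points_and_ties_prefer_balanced_small_t(self):
        conf = np.array([0.3, 0.7])
        y = np.array([0, 1])
        table, best_t = threshold_scan(conf, y)
        assert len(table) == 101
        assert table["threshold"].iloc[0] == 0.0
        assert table["threshold"].iloc[-1] == 1.0
        # every t in (0.3, 0.7] is perfect; tie-break picks the smallest
        assert best_t == pytest.approx(0.31)


class TestConfidenceClass:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (0.92, "very_high"),
            (0.9, "very_high"),
            (0.81, "high"),
            (0.75, "moderate"),
            (0.6, "low"),
            (0.54, "low"),
            (0.5, "below_threshold"),
        ],
    )
    def test_classes_at_default_threshold(self, c, expected):
        assert confidence_class(c, t=0.54) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence_class(1.2)
        with pytest.raises(ValueError):
            confidence_class(0.5, t=0.8)


class TestRunExperiment:
    def _dataset(self, n=300, seed=11, informative=True):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.integers(0, 2, n))
        X = pd.DataFrame(
            {
                "utr_length": rng.normal(size=n) + (y * 3 if informative else 0),
                "kozak_context": rng.normal(size=n) + (y * 2 if informative else 0),
                "utr_frac_A": rng.normal(size=n),
            }
        )
        return X, y

    def test_deterministic_under_fixed_seed(self):
        X, y = self._dataset()
        config = TrainingConfig(n_repeats=3, seed=5)
        r1 = run_experiment(X, y, config)
        r2 = run_experiment(X, y, config)
        pd.testing.assert_frame_equal(r1.runs, r2.runs)
        assert r1.best_model.to_json() == r2.best_model.to_json()

    def test_different_seeds_differ(self):
        X, y = self._dataset()
        r1 = run_experiment(X, y, TrainingConfig(n_repeats=2, seed=5))
        r2 = run_experiment(X, y, TrainingConfig(n_repeats=2, seed=6))
        assert r1.best_model.to_json() != r2.best_model.to_json()

    def test_metrics_within_unit_interval_and_accuracy_identity(self):
        X, y = self._dataset()
        report = run_experiment(X, y, TrainingConfig(n_repeats=3, seed=1))
        metrics = report.runs[
            ["accuracy", "sensitivity", "specificity", "precision", "auc"]
        ]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()
        scan = report.best_scan
        n = scan[["tp", "fp", "tn", "fn"]].iloc[0].sum()
        assert scan["accuracy"].equals((scan["tp"] + scan["tn"]) / n)

    def test_informative_features_learned(self):
        X, y = self._dataset(n=400, seed=13)
        good = run_experiment(X, y, TrainingConfig(n_repeats=3, seed=2))
        assert good.summary.loc["accuracy", "mean"] > 0.9

    def test_permuted_labels_have_no_significant_feature(self):
        # with the labels destroyed, Bonferroni-corrected selection finds
        # nothing and the workflow reports that instead of fitting noise
        X, y = self._dataset(n=400, seed=13)
        rng = np.random.default_rng(14)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        with pytest.raises(NoSignificantFeaturesError):
            run_experiment(
                X, y_perm, TrainingConfig(n_repeats=3, seed=2),
                n_features_total=1252,
            )

    def test_permuted_labels_fit_predicts_at_chance(self):
        # bypassing selection, a model fitted to permuted labels scores at
        # chance level (the test-set threshold scan biases it slightly above)
        from sklearn.model_selection import train_test_split

        X, y = self._dataset(n=2000, seed=15)
        rng = np.random.default_rng(16)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        accs = []
        for rep in range(5):
            tr, te = train_test_split(
                X.index, train_size=0.7, stratify=y_perm, random_state=rep
            )
            model = fit(X.loc[tr], y_perm.loc[tr], TrainingConfig())
            conf = model.predict_confidence(X.loc[te])
            table, t = threshold_scan(conf, y_perm.loc[te].to_numpy())
            accs.append(
                float(table.loc[np.isclose(table["threshold"], t),
                                "accuracy"].iloc[0])
            )
        assert abs(np.mean(accs) - 0.5) < 0.05
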