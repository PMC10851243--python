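"""Baselines, reference representations, repeated CV and report comparison."""

import math

import numpy as np
import pytest

from quantumpairs import (
    BenchmarkConfig,
    CVReport,
    baseline_predictor,
    compare_mannwhitney,
    reference_features,
    relative_metric,
    repeated_cv,
)


class TestBaselines:
    def test_regression_baseline_predicts_training_mean(self):
        model = baseline_predictor("regression", [1.0, 2.0, 3.0])
        np.testing.assert_allclose(model.predict(np.zeros((4, 2))), 2.0)

    def test_regression_baseline_r2_zero_on_training_set(self):
        y = np.array([1.0, 2.0, 3.0, 7.0])
        model = baseline_predictor("regression", y)
        from sklearn.metrics import r2_score

        assert r2_score(y, model.predict(np.zeros((4, 1)))) == pytest.approx(0.0)

    def test_majority_classifier_and_balanced_accuracy(self):
        y_train = np.array([0] * 7 + [1] * 3)
        model = baseline_predictor("classification", y_train)
        assert set(model.predict(np.zeros((5, 1)))) == {0}
        from sklearn.metrics import balanced_accuracy_score

        y_test = np.array([0, 0, 1, 1])
        assert balanced_accuracy_score(
            y_test, model.predict(np.zeros((4, 1)))
        ) == pytest.approx(0.5)

    def test_majority_tie_breaks_toward_smaller_label(self):
        model = baseline_predictor("classification", ["b", "a", "a", "b"])
        assert model.predict(np.zeros((1, 1)))[0] == "a"

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            baseline_predictor("regression", [])


class TestReferenceFeatures:
    MOLS = ["CCO", "CCO", "c1ccccc1"]

    @pytest.mark.parametrize(
        "scheme",
        ["morgan", "atom_pairs_classic", "topological_torsion",
         "path_fingerprint", "descriptor_panel"],
    )
    def test_identical_molecules_get_identical_rows(self, scheme):
        matrix = reference_features(self.MOLS, scheme, n_bits=256)
        np.testing.assert_array_equal(matrix.values[0], matrix.values[1])
        assert np.all(np.isfinite(matrix.values))

    def test_unknown_scheme_lists_valid_ones(self):
        with pytest.raises(ValueError, match="morgan"):
            reference_features(self.MOLS, "daylight")

    def test_ethane_populates_exactly_one_atom_pair_feature(self):
        # cross-check against our own enumeration: ethane has a single pair
        from quantumpairs import enumerate_pairs

        assert sum(enumerate_pairs("CC").values()) == 1
        matrix = reference_features(["CC"], "atom_pairs_classic", n_bits=2048)
        assert np.count_nonzero(matrix.values[0]) == 1
        assert matrix.values[0].sum() == 1.0

    def test_unparseable_molecule_identified_by_row(self):
        with pytest.raises(ValueError, match="bad-row"):
            reference_features(["CC", "xyz"], "morgan", ids=["ok", "bad-row"])


def _toy_regression(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1))
    return x, x[:, 0]  # y equals the single feature


class TestRepeatedCV:
    def test_report_shape_and_determinism(self):
        X, y = _toy_regression()
        config = BenchmarkConfig(task="regression", n_estimators=30, random_seed=5)
        r1 = repeated_cv(X, y, config)
        r2 = repeated_cv(X, y, config)
        for metric in config.metrics:
            assert r1.per_fold[metric].shape == (10, 10)
            assert r1.values(metric).size == 100
            np.testing.assert_array_equal(r1.per_fold[metric], r2.per_fold[metric])

    def test_perfectly_predictive_feature_recovers_target(self):
        X, y = _toy_regression(n=200, seed=1)
        config = BenchmarkConfig(
            task="regression", n_estimators=50, n_repeats=2, random_seed=2
        )
        report = repeated_cv(X, y, config)
        assert report.summary()["r2"]["mean"] >= 0.99

    def test_baseline_regressor_has_nonpositive_heldout_r2(self):
        X, y = _toy_regression(n=150, seed=3)
        config = BenchmarkConfig(
            task="regression", n_repeats=2, random_seed=3
        )
        report = repeated_cv(X, y, config, model="baseline")
        assert report.summary()["r2"]["mean"] <= 0.01
        assert np.all(report.values("rmse") >= 0)

    def test_label_independent_classifier_has_chance_auc(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 3))
        y = np.array([0, 1] * 60)
        config = BenchmarkConfig(task="classification", random_seed=4)
        report = repeated_cv(X, y, config, model="baseline")
        auc = report.summary()["roc_auc"]["mean"]
        assert abs(auc - 0.5) <= 0.05
        assert np.all((report.values("balanced_accuracy") >= 0)
                      & (report.values("balanced_accuracy") <= 1))

    def test_stratified_folds_keep_both_classes_in_training(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(130, 2))
        y = np.zeros(130, dtype=int)
        y[:10] = 1  # 1:12 imbalance
        config = BenchmarkConfig(
            task="classification", n_estimators=20, n_repeats=2, random_seed=5
        )
        report = repeated_cv(X, y, config)  # would crash without stratification
        assert report.values("roc_auc").size == 20

    def test_misaligned_and_degenerate_inputs_rejected(self):
        X, y = _toy_regression()
        config = BenchmarkConfig(task="regression")
        with pytest.raises(ValueError, match="misaligned"):
            repeated_cv(X, y[:-1], config)
        with pytest.raises(ValueError, match="binary"):
            repeated_cv(X, y, BenchmarkConfig(task="classification"))
        with pytest.raises(ValueError, match="rows"):
            repeated_cv(X[:5], y[:5], config)

    def test_report_json_roundtrip(self, tmp_path):
        X, y = _toy_regression()
        config = BenchmarkConfig(task="regression", n_estimators=10,
                                 n_repeats=2, random_seed=6)
        report = repeated_cv(X, y, config, representation="toy")
        path = tmp_path / "report.json"
        report.save(path)
        loaded = CVReport.load(path)
        assert loaded.representation == "toy"
        assert loaded.config == config
        for metric in config.metrics:
            np.testing.assert_array_equal(loaded.per_fold[metric],
                                          report.per_fold[metric])


def _fake_report(values, seed=0, metric="r2"):
    values = np.asarray(values, dtype=float)
    config = BenchmarkConfig(
        task="regression",
        n_repeats=values.shape[0],
        n_folds=values.shape[1],
        random_seed=seed,
        metrics=("r2",),
    )
    return CVReport(representation="fake", config=config, per_fold={metric: values})


class TestComparison:
    def test_self_comparison_is_identically_zero(self):
        report = _fake_report(np.random.default_rng(1).uniform(0.3, 0.9, (10, 10)))
        result = relative_metric(report, report, "r2")
        assert np.all(result.per_fold_relative == 0.0)
        assert result.per_fold_relative.size == 100
        assert result.n_dropped == 0

    def test_hand_computed_ratio(self):
        a = _fake_report(np.full((2, 5), 0.53))
        b = _fake_report(np.full((2, 5), 0.50))
        result = relative_metric(a, b, "r2")
        np.testing.assert_allclose(result.per_fold_relative, 0.06)

    def test_zero_denominator_folds_are_dropped_and_counted(self):
        a = _fake_report(np.ones((1, 4)))
        values = np.ones((1, 4)); values[0, 2] = 0.0
        b = _fake_report(values)
        result = relative_metric(a, b, "r2")
        assert result.n_dropped == 1 and result.per_fold_relative.size == 3

    def test_structural_mismatch_rejected(self):
        a = _fake_report(np.ones((2, 5)))
        b = _fake_report(np.ones((1, 5)))
        with pytest.raises(ValueError, match="mismatch"):
            relative_metric(a, b, "r2")

    def test_identical_samples_not_significant(self):
        report = _fake_report(np.random.default_rng(2).uniform(0, 1, (10, 10)))
        result = compare_mannwhitney(report, report, "r2")
        assert result.p_value == pytest.approx(1.0)
        assert result.significant is False

    def test_all_constant_samples_take_p_equals_one_path(self):
        report = _fake_report(np.full((3, 4), 0.7))
        result = compare_mannwhitney(report, report, "r2")
        assert result.p_value == 1.0
        assert result.u_statistic == 12 * 12 / 2

    def test_fully_separated_samples_match_exact_enumeration(self):
        # 10 vs 10, complete separation: every one of C(20,10) orderings is
        # equally likely under the null, only the two extremes are as extreme.
        a = _fake_report(np.arange(1, 11, dtype=float).reshape(1, 10))
        b = _fake_report(np.arange(101, 111, dtype=float).reshape(1, 10))
        result = compare_mannwhitney(a, b, "r2")
        exact = 2.0 / math.comb(20, 10)
        assert result.p_value == pytest.approx(exact, rel=1e-9)
        assert result.significant is True

    def test_plot_helper_writes_figure(self, tmp_path):
        from quantumpairs import BenchmarkConfig
        from quantumpairs.benchmark import plot_metric_bars

        reports = [_fake_report(np.random.default_rng(k).uniform(0.4, 0.9, (2, 5)))
                   for k in range(3)]
        out = tmp_path / "bars.png"
        plot_metric_bars(reports, "r2", out)
        assert out.stat().st_size > 0

    def test_alpha_flag_honored(self):
        a = _fake_report(np.arange(1, 11, dtype=float).reshape(1, 10))
        b = _fake_report(np.arange(101, 111, dtype=float).reshape(1, 10))
        strict = compare_mannwhitney(a, b, "r2", alpha=1e-9)
        assert strict.significant is False
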