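"""Classifier fusion stage: table IO, training, importance, RFE, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from driverfuse import fusion, synthetic_data
from driverfuse.fusion import FeatureTable, FusionConfig


def make_table(n=400, separations=None, n_noise=0, seed=0, correlation=0.0):
    spec = synthetic_data.SyntheticDatasetSpec.scaled(
        n, seed=seed,
        separations=separations or {"A": 3.0, "B": 3.0},
        n_noise_features=n_noise,
        feature_correlation=correlation,
    )
    ds = synthetic_data.generate_dataset(spec)
    return ds.features


class TestReadFeatureTable:
    def test_five_row_fixture_with_na(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "key\tlabel\tRadialSVM\tLR\n"
            "v1\tdriver\t0.9\t0.8\n"
            "v2\tpassenger\t0.1\tNA\n"
            "v3\tDriver\t0.5\t0.4\n"
            "v4\tpassenger\t0.2\t0.1\n"
            "v5\tdriver\t0.7\t0.9\n"
        )
        table = fusion.read_feature_table(p)
        assert len(table.df) == 5
        assert table.df["LR"].isna().sum() == 1
        assert table.df.loc[2, "label"] == "driver"  # case-normalized

    def test_duplicate_key_raises(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("key\tlabel\tx\nv1\tdriver\t1\nv1\tpassenger\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            fusion.read_feature_table(p)

    def test_non_numeric_cell_reports_location(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("key\tlabel\tx\nv1\tdriver\t1\nv2\tpassenger\toops\n")
        with pytest.raises(ValueError, match="x"):
            fusion.read_feature_table(p)


class TestAttachDlScore:
    def make_scores(self, keys, values):
        return pd.DataFrame({"key": keys, "score": values})

    def test_full_overlap_adds_one_column(self):
        table = make_table(n=50)
        scores = self.make_scores(table.df["key"], np.linspace(0, 1, 50))
        out = fusion.attach_dl_score(table, scores)
        assert len(out.df) == 50
        assert "DL_score" in out.feature_columns

    def test_partial_overlap_inner_join(self):
        table = make_table(n=50)
        scores = self.make_scores(table.df["key"][:20], np.linspace(0, 1, 20))
        out = fusion.attach_dl_score(table, scores, join="inner")
        assert len(out.df) == 20

    def test_zero_overlap_raises(self):
        table = make_table(n=20)
        scores = self.make_scores(["nope:1:A>G"], [0.5])
        with pytest.raises(ValueError, match="no variant keys"):
            fusion.attach_dl_score(table, scores)


class TestTrainClassifier:
    @pytest.mark.parametrize("algorithm", fusion.ALGORITHMS)
    def test_strong_separation_high_f1(self, algorithm):
        table = make_table(n=2000, separations={"A": 3.0, "B": 3.0}, seed=1)
        fitted = fusion.train_classifier(table, algorithm, FusionConfig(seed=1))
        assert fitted.report.f1 >= 0.9

    def test_permuted_labels_null_auc(self):
        aucs = []
        for seed in range(5):
            table = make_table(n=600, separations={"A": 0.0, "B": 0.0}, n_noise=5, seed=seed)
            fitted = fusion.train_classifier(table, "random_forest", FusionConfig(seed=seed))
            aucs.append(fitted.report.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_constant_features_auc_half(self):
        df = pd.DataFrame({
            "key": [f"v{i}" for i in range(100)],
            "label": ["driver", "passenger"] * 50,
            "flat": np.ones(100),
        })
        fitted = fusion.train_classifier(FeatureTable(df), "random_forest", FusionConfig(seed=0))
        assert fitted.report.auc == 0.5

    def test_split_reproducible_across_algorithms(self):
        table = make_table(n=300, seed=2)
        rf = fusion.train_classifier(table, "random_forest", FusionConfig(seed=7))
        svm = fusion.train_classifier(table, "svm", FusionConfig(seed=7))
        assert np.array_equal(np.sort(rf.holdout_index), np.sort(svm.holdout_index))

    def test_single_class_raises(self):
        df = pd.DataFrame({"key": ["a", "b"], "label": ["driver", "driver"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fusion.train_classifier(FeatureTable(df), "random_forest")


class TestFeatureImportance:
    def test_single_informative_feature_ranks_first(self):
        table = make_table(n=2000, separations={"signal": 2.0}, n_noise=9, seed=3)
        fitted = fusion.train_classifier(table, "random_forest", FusionConfig(seed=3))
        report = fusion.feature_importance(fitted)
        assert report.importances.index[0] == "signal"

    def test_importances_sum_to_one(self):
        table = make_table(n=300, seed=4)
        fitted = fusion.train_classifier(table, "gradient_boosted_trees", FusionConfig(seed=4))
        assert fusion.feature_importance(fitted).importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_svm_has_no_impurity_importance(self):
        table = make_table(n=200, seed=5)
        fitted = fusion.train_classifier(table, "svm", FusionConfig(seed=5))
        with pytest.raises(ValueError, match="tree ensembles"):
            fusion.feature_importance(fitted)

    def test_duplicated_column_shares_importance(self):
        table = make_table(n=2000, separations={"signal": 2.0}, n_noise=5, seed=6)
        single = fusion.feature_importance(
            fusion.train_classifier(table, "random_forest", FusionConfig(seed=6))
        ).importances["signal"]
        dup_df = table.df.copy()
        dup_df["signal_copy"] = dup_df["signal"]
        dup = fusion.feature_importance(
            fusion.train_classifier(FeatureTable(dup_df), "random_forest", FusionConfig(seed=6))
        ).importances
        combined = dup["signal"] + dup["signal_copy"]
        assert combined == pytest.approx(single, abs=0.15)


class TestRecursiveFeatureElimination:
    def test_identity_subset(self):
        table = make_table(n=200, seed=7)
        k = len(table.feature_columns)
        ranked, eliminated = fusion.recursive_feature_elimination(table, "random_forest", k)
        assert sorted(ranked) == sorted(table.feature_columns)
        assert eliminated == []

    def test_recovers_planted_informative_features(self):
        hits = 0
        for seed in range(5):
            table = make_table(
                n=2000, separations={"s1": 1.5, "s2": 1.5, "s3": 1.5}, n_noise=7, seed=seed
            )
            ranked, _ = fusion.recursive_feature_elimination(
                table, "random_forest", 3, FusionConfig(seed=seed)
            )
            if set(ranked) == {"s1", "s2", "s3"}:
                hits += 1
        assert hits >= 4

    def test_k1_keeps_single_informative_feature(self):
        table = make_table(n=1500, separations={"signal": 2.0}, n_noise=6, seed=8)
        ranked, _ = fusion.recursive_feature_elimination(table, "random_forest", 1, FusionConfig(seed=8))
        assert ranked == ["signal"]

    def test_k_out_of_range(self):
        table = make_table(n=100, seed=9)
        with pytest.raises(ValueError):
            fusion.recursive_feature_elimination(table, "random_forest", 99)


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        table = make_table(n=100, seed=10)
        corr = fusion.spearman_matrix(table)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_reversed_ranks_give_minus_one(self):
        df = pd.DataFrame({
            "key": list("abcde"), "label": ["driver", "passenger"] * 2 + ["driver"],
            "x": [1.0, 2, 3, 4, 5], "y": [5.0, 4, 3, 2, 1],
        })
        corr = fusion.spearman_matrix(FeatureTable(df))
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)); d = (1,1,1,1,0) -> 1 - 24/120 = 0.8
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        expected = 1 - 6 * d2 / (5 * (25 - 1))
        df = pd.DataFrame({
            "key": list("abcde"), "label": ["driver", "passenger"] * 2 + ["driver"],
            "x": x, "y": y,
        })
        corr = fusion.spearman_matrix(FeatureTable(df))
        assert corr.loc["x", "y"] == pytest.approx(expected)
        assert corr.loc["x", "y"] == pytest.approx(spearmanr(x, y).statistic)

    def test_zero_variance_column_is_nan_with_warning(self):
        df = pd.DataFrame({
            "key": list("abcd"), "label": ["driver", "passenger"] * 2,
            "x": [1.0, 2, 3, 4], "flat": [1.0, 1, 1, 1],
        })
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = fusion.spearman_matrix(FeatureTable(df))
        assert np.isnan(corr.loc["x", "flat"])


def test_information_value_prefers_informative_feature():
    table = make_table(n=1000, separations={"signal": 2.0}, n_noise=3, seed=11)
    iv = fusion.information_value_report(table)
    assert iv.index[0] == "signal"
    assert iv["signal"] > max(iv[c] for c in iv.index if c != "signal")


def test_profiles_select_expected_columns():
    assert fusion.PROFILES["top3"] == ["RadialSVM", "LR", "DL_score"]
    assert len(fusion.PROFILES["top8"]) == 8
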