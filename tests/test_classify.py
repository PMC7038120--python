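"""Classification and evaluation: design-matrix shapes, metric arithmetic,
cross-validation mechanics, and leakage properties."""
import numpy as np
import pandas as pd
import pytest

from patype.classify import (
    ConfusionMatrix,
    ModelSpec,
    build_design_matrix,
    compute_metrics,
    feature_importance_report,
    kfold_cv,
    loso_cv,
    round_half_up,
    train_rf,
)
from patype.core import GROUPED_CLASSES, POSITIONS
from patype.features import FEATURE_NAMES, GPS_FEATURE_NAMES
from patype.worked_examples import CLASS_ORDER, CONFUSION_COUNTS, PRINTED_METRICS


def toy_features(n_subjects=4, per_class=6, seed=0, separable=True, subject_shift=0.0):
    """Tiny wide feature table: two informative columns + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        shift = subject_shift * rng.normal()
        for label in ("walking", "sitting", "running"):
            mu = {"walking": 1.0, "sitting": 0.0, "running": 2.0}[label]
            for j in range(per_class):
                row = {
                    "subject": f"S{si}",
                    "protocol": "semi_structured" if j % 2 == 0 else "real_life",
                    "environment": "leisure",
                    "t_start": float(j),
                    "t_end": float(j + 1),
                    "label": label,
                }
                for pos in POSITIONS:
                    for k, name in enumerate(FEATURE_NAMES):
                        if k == 0:
                            v = (mu if separable else 0.0) + shift + 0.1 * rng.normal()
                        elif k == 1:
                            v = mu * 0.5 + shift + 0.1 * rng.normal()
                        else:
                            v = rng.normal()
                        row[f"{pos}__{name}"] = v
                row["gps_mean_speed"] = mu + 0.05 * rng.normal()
                row["gps_elev_diff"] = 0.0
                rows.append(row)
    return pd.DataFrame(rows)


class TestDesignMatrix:
    def test_general_acc_has_425_columns(self):
        X, y, subjects, _ = build_design_matrix(toy_features(), ModelSpec(scope="general"))
        assert X.shape[1] == 425

    def test_individual_acc_has_85_columns(self):
        X, *_ = build_design_matrix(toy_features(), ModelSpec(scope="knee"))
        assert X.shape[1] == 85

    def test_individual_acc_gps_has_87_columns(self):
        X, *_ = build_design_matrix(toy_features(), ModelSpec(scope="knee", feature_set="acc_gps"))
        assert X.shape[1] == 87

    def test_general_acc_gps_has_427_columns(self):
        X, *_ = build_design_matrix(toy_features(), ModelSpec(scope="general", feature_set="acc_gps"))
        assert X.shape[1] == 427

    def test_gps_missing_rows_excluded_or_zeroed(self):
        df = toy_features()
        df.loc[:3, "gps_mean_speed"] = np.nan
        X_ex, *_ = build_design_matrix(df, ModelSpec(scope="knee", feature_set="acc_gps"))
        assert len(X_ex) == len(df) - 4
        X_z, *_ = build_design_matrix(
            df, ModelSpec(scope="knee", feature_set="acc_gps", gps_missing_policy="zero")
        )
        assert len(X_z) == len(df)
        assert (X_z["gps_mean_speed"].iloc[:4] == 0.0).all()

    def test_missing_columns_reported(self):
        df = toy_features().drop(columns=["knee__time_mean_x"])
        with pytest.raises(ValueError, match="knee__time_mean_x"):
            build_design_matrix(df, ModelSpec(scope="knee"))


class TestTrainRf:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        df = toy_features()
        X, y, *_ = build_design_matrix(df, ModelSpec(scope="chest"))
        model = train_rf(X, y, n_trees=50, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_fixed_seed_reproduces_importance_ranking(self):
        df = toy_features()
        X, y, *_ = build_design_matrix(df, ModelSpec(scope="chest"))
        r1 = feature_importance_report(train_rf(X, y, n_trees=50, seed=3), list(X.columns))
        r2 = feature_importance_report(train_rf(X, y, n_trees=50, seed=3), list(X.columns))
        assert r1 == r2
        assert len(r1) == 10

    def test_informative_feature_ranks_high(self):
        df = toy_features()
        X, y, *_ = build_design_matrix(df, ModelSpec(scope="chest"))
        top = feature_importance_report(train_rf(X, y, n_trees=100, seed=0), list(X.columns), top_n=3)
        informative = {f"chest__{FEATURE_NAMES[0]}", f"chest__{FEATURE_NAMES[1]}"}
        assert informative & set(top)

    def test_single_class_labels_rejected(self):
        df = toy_features()
        df["label"] = "walking"
        X, y, *_ = build_design_matrix(df, ModelSpec(scope="chest"))
        with pytest.raises(ValueError):
            train_rf(X, y)


class TestMetrics:
    @pytest.mark.parametrize("key", sorted(CONFUSION_COUNTS))
    def test_worked_examples_reproduced_exactly(self, key):
        """Every printed recall/precision/F1 cell of the four published
        worked-example confusion matrices is reproduced after half-up
        integer rounding."""
        report = compute_metrics(ConfusionMatrix(CLASS_ORDER, CONFUSION_COUNTS[key]))
        rounded = report.rounded()
        for i, cls in enumerate(CLASS_ORDER):
            recall, precision, f1 = PRINTED_METRICS[key][i]
            assert rounded.loc[cls, "recall"] == recall, (key, cls)
            assert rounded.loc[cls, "precision"] == precision, (key, cls)
            assert rounded.loc[cls, "f1"] == f1, (key, cls)

    def test_perfect_diagonal_gives_all_100(self):
        cm = ConfusionMatrix(GROUPED_CLASSES, np.diag([5] * 7))
        report = compute_metrics(cm)
        assert report.accuracy == 100.0
        assert (report.rounded() == 100).all().all()

    def test_one_vs_rest_conservation(self):
        counts = CONFUSION_COUNTS["s1_acc"]
        total = counts.sum()
        for i in range(7):
            tp = counts[i, i]
            fp = counts[i].sum() - tp
            fn = counts[:, i].sum() - tp
            tn = total - tp - fp - fn
            assert tp + fp == counts[i].sum()
            assert tp + fn == counts[:, i].sum()
            assert tp + tn + fp + fn == total

    def test_empty_row_and_column_give_zero_metrics(self):
        counts = np.zeros((7, 7), int)
        counts[0, 0] = 3
        report = compute_metrics(ConfusionMatrix(GROUPED_CLASSES, counts))
        assert report.per_class.iloc[1:].sum().sum() == 0.0

    def test_negative_counts_rejected(self):
        counts = -np.ones((7, 7), int)
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(GROUPED_CLASSES, counts))

    def test_round_half_up(self):
        assert round_half_up(92.5) == 93
        assert round_half_up(92.49) == 92
        assert round_half_up(98.507) == 99


class TestCrossValidation:
    def test_loso_has_one_fold_per_subject_and_no_leakage(self):
        df = toy_features(n_subjects=3)
        spec = ModelSpec(scope="chest", n_trees=20)
        report = loso_cv(df, spec)
        assert set(report.per_subject) == {"S0", "S1", "S2"}
        assert report.confusion.total == (df["protocol"].isin(["semi_structured", "real_life"])).sum()

    def test_identical_subjects_loso_near_within_subject_accuracy(self):
        df = toy_features(n_subjects=4, subject_shift=0.0)
        spec = ModelSpec(scope="chest", n_trees=50)
        loso = loso_cv(df, spec)
        kfold = kfold_cv(df, spec, k=4, seed=0)
        assert abs(loso.accuracy - kfold.accuracy) < 15.0

    def test_kfold_reproducible_under_fixed_seed(self):
        df = toy_features()
        spec = ModelSpec(scope="chest", n_trees=20)
        a = kfold_cv(df, spec, k=4, seed=5)
        b = kfold_cv(df, spec, k=4, seed=5)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)

    def test_k_exceeding_segment_count_rejected(self):
        df = toy_features(n_subjects=1, per_class=2)
        with pytest.raises(ValueError):
            kfold_cv(df, ModelSpec(scope="chest", n_trees=10), k=100)

    def test_scenario_s1_trains_on_semi_structured_only(self):
        df = toy_features(n_subjects=3)
        spec = ModelSpec(scope="chest", scenario="S1_semi_structured", n_trees=20)
        report = loso_cv(df, spec, test_on="training_protocol")
        assert report.confusion.total == (df["protocol"] == "semi_structured").sum()

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        df = toy_features(n_subjects=6, per_class=8)
        df["label"] = rng.permutation(df["label"].to_numpy())
        report = loso_cv(df, ModelSpec(scope="chest", n_trees=30))
        assert report.accuracy < 55.0  # chance is ~33% over 3 classes
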