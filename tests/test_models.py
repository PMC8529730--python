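import numpy as np
import pandas as pd
import pytest

from _helpers import null_feature_frame, separable_feature_frame
from picme.errors import DegenerateDataError, InputError
from picme.evaluate import roc_auc
from picme.models import (
    LabeledDataset,
    RFSpec,
    SVMSpec,
    grid_search_svm,
    load_model,
    predict,
    save_model,
    train_rf,
    train_svm_fixed,
)

SMALL_SVM_SPEC = SVMSpec(
    c_grid=tuple(np.logspace(-2, 4, 7)),
    g_grid=tuple(np.logspace(-4, 1, 6)),
    refine_rounds=1,
)


class TestLabeledDataset:
    def test_duplicate_pair_keys_rejected(self):
        df = separable_feature_frame(5)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(InputError, match="duplicate"):
            LabeledDataset(dup)

    def test_only_twilight_passing_rows_eligible(self):
        df = separable_feature_frame(5)
        df.loc[0, "tz_pass"] = False
        assert len(LabeledDataset(df).eligible()) == len(df) - 1


class TestRandomForest:
    def test_same_seed_gives_identical_scores(self):
        data = LabeledDataset(separable_feature_frame(20))
        probe = null_feature_frame(30, seed=5)
        m1 = train_rf(data, RFSpec(n_trees=100, seed=3))
        m2 = train_rf(data, RFSpec(n_trees=100, seed=3))
        np.testing.assert_array_equal(
            m1.score_rows(probe[["ss", "iccb", "mmf", "eld"]].to_numpy()),
            m2.score_rows(probe[["ss", "iccb", "mmf", "eld"]].to_numpy()),
        )

    def test_separable_features_rank_perfectly(self):
        df = separable_feature_frame(40)
        data = LabeledDataset(df)
        model = train_rf(data, RFSpec(seed=0))
        scores = model.score_rows(df[["ss", "iccb", "mmf", "eld"]].to_numpy())
        y = (df["label"] == "paralog").astype(int).to_numpy()
        assert roc_auc(scores, y)[1] == 1.0

    def test_constant_feature_trains_with_negligible_importance(self):
        df = separable_feature_frame(30)
        df["eld"] = 1.0
        model = train_rf(LabeledDataset(df), RFSpec(seed=0))
        importances = dict(zip(model.feature_names, model.estimator.feature_importances_))
        assert importances["eld"] < 0.01

    def test_single_class_rejected(self):
        df = separable_feature_frame(10)
        df["label"] = "paralog"
        with pytest.raises(DegenerateDataError):
            train_rf(LabeledDataset(df))


class TestSvmGridSearch:
    def test_default_initial_grid_has_399_points(self, monkeypatch):
        import picme.models as models_mod

        spec = SVMSpec()
        evaluated = []
        real = models_mod._cv_accuracy

        def counting(X, y, C, g, folds, seed):
            evaluated.append((C, g))
            return real(X, y, C, g, folds, seed)

        monkeypatch.setattr(models_mod, "_cv_accuracy", counting)
        data = LabeledDataset(separable_feature_frame(10))
        grid_search_svm(data, SVMSpec(refine_rounds=0), seed=0)
        assert len(evaluated) == len(spec.c_grid) * len(spec.g_grid) == 21 * 19

    def test_no_signal_data_gives_chance_level_cv_accuracy(self):
        data = LabeledDataset(null_feature_frame(200, seed=0))
        model = grid_search_svm(data, SMALL_SVM_SPEC, seed=0)
        assert abs(model.params["cv_accuracy"] - 0.5) <= 0.1

    def test_separable_data_reaches_perfect_training_accuracy(self):
        df = separable_feature_frame(20)
        data = LabeledDataset(df)
        model = grid_search_svm(data, SMALL_SVM_SPEC, seed=0)
        X = df[["ss", "iccb", "mmf", "eld"]].to_numpy()
        calls = (model.score_rows(X) > 0.5).astype(int)
        y = (df["label"] == "paralog").astype(int).to_numpy()
        assert np.mean(calls == y) == 1.0

    def test_too_few_rows_per_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            grid_search_svm(LabeledDataset(separable_feature_frame(5)), SMALL_SVM_SPEC)

    def test_grid_must_be_increasing(self):
        with pytest.raises(InputError):
            SVMSpec(c_grid=(1.0, 0.1))


class TestPredict:
    def test_sub_twilight_rows_marked_unclassifiable(self):
        df = separable_feature_frame(20)
        model = train_rf(LabeledDataset(df), RFSpec(n_trees=50, seed=0))
        probe = separable_feature_frame(5, seed=9)
        probe.loc[1, "tz_pass"] = False
        calls = predict(model, probe)
        assert calls.loc[1, "call"] == "unclassifiable"
        assert np.isnan(calls.loc[1, "score"])
        assert set(calls.loc[calls.index != 1, "call"]) <= {"paralog", "isoform"}

    def test_scores_invariant_under_row_permutation(self):
        df = separable_feature_frame(20)
        model = train_rf(LabeledDataset(df), RFSpec(n_trees=50, seed=0))
        probe = separable_feature_frame(10, seed=4)
        perm = np.random.default_rng(0).permutation(len(probe))
        straight = predict(model, probe)
        shuffled = predict(model, probe.iloc[perm].reset_index(drop=True))
        merged = straight.merge(shuffled, on=["id1", "id2"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["score_a"], merged["score_b"])

    def test_heavily_represented_paralog_scores_high(self):
        df = separable_feature_frame(40)
        model = train_rf(LabeledDataset(df), RFSpec(seed=0))
        probe = df[df["label"] == "paralog"].head(1).copy()
        assert predict(model, probe)["score"].iloc[0] > 0.5

    def test_missing_feature_column_rejected(self):
        df = separable_feature_frame(10)
        model = train_rf(LabeledDataset(df), RFSpec(n_trees=10, seed=0))
        with pytest.raises(InputError, match="missing"):
            predict(model, df.drop(columns=["mmf"]))


class TestStandardizationAndPersistence:
    def test_scaler_fitted_on_training_rows_only(self):
        df = separable_feature_frame(20)
        model = train_svm_fixed(LabeledDataset(df), seed=0)
        X = df[["ss", "iccb", "mmf", "eld"]].to_numpy()
        np.testing.assert_allclose(model.scaler.mean_, X.mean(axis=0))
        # scoring training data after a column round-trip is identity-stable
        s1 = model.score_rows(X)
        s2 = model.score_rows(pd.DataFrame(X).to_numpy())
        np.testing.assert_array_equal(s1, s2)

    def test_model_round_trip_through_disk(self, tmp_path):
        df = separable_feature_frame(15)
        model = train_rf(LabeledDataset(df), RFSpec(n_trees=25, seed=1))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        X = df[["ss", "iccb", "mmf", "eld"]].to_numpy()
        np.testing.assert_array_equal(model.score_rows(X), back.score_rows(X))
        assert back.params == model.params


class TestRfVersusSvmBenchmark:
    def test_rf_tracks_or_beats_fixed_svm_on_benchmark(self):
        """Across 10 seeded benchmark draws the RF is consistently strong
        (mean held-out AUC >= 0.9) and never materially below an SVM with
        fixed (C, g) = (1, 1/4) on the same split.

        On this synthetic benchmark both classifiers approach AUC 1.0, so a
        strict RF > SVM ordering is not observable; consistency and
        non-inferiority are the testable residue of the RF-vs-SVM contrast.
        """
        from picme.evaluate import half_split
        from picme.features import MODEL_FEATURES
        from picme.pipeline import simulated_feature_table
        from picme.simulate import SimParams

        for seed in range(10):
            df = simulated_feature_table(SimParams(n_pairs=300, seed=seed))
            elig = df[df["tz_pass"]].reset_index(drop=True)
            y = (elig["label"] == "paralog").to_numpy(int)
            split = half_split(y, seed)
            train = LabeledDataset(elig.iloc[split.train_index])
            rf = train_rf(train, RFSpec(seed=seed))
            svm = train_svm_fixed(train, C=1.0, gamma=0.25, seed=seed)

            def mean_auc(model):
                aucs = []
                for fold in split.test_folds:
                    X = elig.iloc[fold][MODEL_FEATURES].to_numpy(float)
                    aucs.append(roc_auc(model.score_rows(X), y[fold])[1])
                return float(np.mean(aucs))

            rf_auc, svm_auc = mean_auc(rf), mean_auc(svm)
            assert rf_auc >= 0.9
            assert rf_auc >= svm_auc - 0.02
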