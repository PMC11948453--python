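"""SVM protocol: features, balancing, CV, prediction, structural rates."""

import numpy as np
import pandas as pd
import pytest

import porecount as pc
from porecount.classify import FEATURE_NAMES, LabeledFeatureSet, SVMConfig


def gaussian_set(means, n=400, sd=1.0, seed=0):
    """Synthetic 3-feature Gaussian classes at the given mean vectors."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(m, sd, size=(n, 3)) for m in means])
    y = np.concatenate([np.full(n, i) for i in range(len(means))])
    return LabeledFeatureSet(X, y)


class TestBuildFeatures:
    def test_log_dwell_identity(self):
        df = pd.DataFrame({"I_B": [0.8], "t_D_us": [1000.0],
                           "i_rms_nA": [0.2], "label": ["mtDNA"]})
        fs = pc.build_features(df)
        assert fs.X[0, 1] == pytest.approx(3.0)
        assert fs.y[0] == 1

    def test_zscore_standardization_properties(self, three_class_features):
        from sklearn.preprocessing import StandardScaler

        Xz = StandardScaler().fit_transform(three_class_features.X)
        assert np.allclose(Xz.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xz.std(axis=0), 1.0, atol=1e-9)

    def test_stored_standardization_applies_training_statistics(self, three_class_features):
        art = pc.train_svm(three_class_features, SVMConfig(seed=0))
        shifted = three_class_features.X + 5.0
        z = art.scaler.transform(shifted)
        # shifted data standardized with training stats keeps the offset
        assert (z.mean(axis=0) > 2.0).all()

    def test_nonpositive_dwell_rejected(self):
        df = pd.DataFrame({"I_B": [0.8], "t_D_us": [0.0],
                           "i_rms_nA": [0.2], "label": ["mtDNA"]})
        with pytest.raises(ValueError):
            pc.build_features(df)


class TestBalanceClasses:
    def test_downsamples_to_minority(self, rng):
        X = rng.normal(size=(2200, 3))
        y = np.array([0] * 1000 + [1] * 500 + [2] * 700)
        out = pc.balance_classes(LabeledFeatureSet(X, y), seed=1)
        assert out.class_counts() == {0: 500, 1: 500, 2: 500}

    def test_balanced_input_is_permutation(self, rng):
        X = rng.normal(size=(600, 3))
        y = np.array([0] * 300 + [1] * 300)
        out = pc.balance_classes(LabeledFeatureSet(X, y), seed=2)
        order = np.lexsort(X.T), np.lexsort(out.X.T)
        assert np.array_equal(X[order[0]], out.X[order[1]])

    def test_seed_changes_subset_not_counts(self, rng):
        X = rng.normal(size=(900, 3))
        y = np.array([0] * 600 + [1] * 300)
        a = pc.balance_classes(LabeledFeatureSet(X, y), seed=1)
        b = pc.balance_classes(LabeledFeatureSet(X, y), seed=2)
        assert a.class_counts() == b.class_counts() == {0: 300, 1: 300}
        assert not np.array_equal(a.X, b.X)

    def test_empty_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            pc.balance_classes(LabeledFeatureSet(X, np.zeros(10, int)), seed=0)


class TestTrainPredict:
    def test_separable_classes_train_perfectly(self):
        fs = gaussian_set([[0, 0, 0], [10, 10, 10]], sd=0.5)
        art = pc.train_svm(fs, SVMConfig(seed=0))
        labels, scores = pc.predict(art, fs)
        assert (labels == fs.y).all()
        assert scores.shape == (len(fs), 2)

    def test_chance_level_on_identical_distributions(self):
        fs = gaussian_set([[0, 0, 0], [0, 0, 0]], n=1000, seed=3)
        rep = pc.cross_validate(fs, SVMConfig(seed=3))
        se = 100.0 * np.sqrt(0.25 / len(fs))
        assert abs(rep.accuracy_pct - 50.0) < 3 * se

    def test_prediction_equivariant_under_row_permutation(self):
        fs = gaussian_set([[0, 0, 0], [3, 3, 3]], n=100, seed=4)
        art = pc.train_svm(fs, SVMConfig(seed=0))
        perm = np.random.default_rng(0).permutation(len(fs))
        labels, _ = pc.predict(art, fs.X)
        labels_p, _ = pc.predict(art, fs.X[perm])
        assert np.array_equal(labels[perm], labels_p)

    def test_schema_mismatch_rejected(self, three_class_features):
        art = pc.train_svm(three_class_features, SVMConfig(seed=0))
        with pytest.raises(ValueError, match="schema"):
            pc.predict(art, np.zeros((5, 2)))

    def test_artifact_roundtrip(self, three_class_features, tmp_path):
        art = pc.train_svm(three_class_features, SVMConfig(seed=0))
        art.save(tmp_path / "model.pkl")
        loaded = pc.SVMArtifact.load(tmp_path / "model.pkl")
        a, _ = pc.predict(art, three_class_features)
        b, _ = pc.predict(loaded, three_class_features)
        assert np.array_equal(a, b)


class TestCrossValidate:
    def test_confusion_rows_sum_to_class_counts(self, three_class_features):
        rep = pc.cross_validate(three_class_features, SVMConfig(seed=1))
        counts = three_class_features.class_counts()
        for i, c in enumerate(rep.classes):
            assert rep.confusion[i].sum() == counts[int(c)]
            assert rep.tpr[int(c)] + rep.fnr[int(c)] == pytest.approx(1.0)

    def test_perfectly_separable_data_scores_100(self):
        fs = gaussian_set([[0, 0, 0], [20, 20, 20], [-20, 20, 0]], sd=0.3)
        rep = pc.cross_validate(fs, SVMConfig(seed=2))
        assert rep.accuracy_pct == 100.0
        assert np.array_equal(rep.confusion, np.diag(rep.confusion.diagonal()))

    def test_fixed_seed_reproduces_report(self, three_class_features):
        r1 = pc.cross_validate(three_class_features, SVMConfig(seed=5))
        r2 = pc.cross_validate(three_class_features, SVMConfig(seed=5))
        assert np.array_equal(r1.confusion, r2.confusion)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_accuracy_degrades_monotonically_with_separation(self):
        accs = []
        for sep in (3.0, 1.5, 0.5):
            fs = gaussian_set([[0, 0, 0], [sep, sep, sep]], n=600, seed=6)
            accs.append(pc.cross_validate(fs, SVMConfig(seed=6)).accuracy_pct)
        assert accs[0] > accs[1] > accs[2]

    def test_fold_internal_standardization_differs_from_global(self):
        # a drifted feature makes fold statistics differ from global ones
        rng = np.random.default_rng(7)
        n = 300
        X = rng.normal(size=(2 * n, 3))
        X[:, 0] += np.linspace(0, 30, 2 * n)
        y = np.array([0, 1] * n)
        fs = LabeledFeatureSet(X, y)
        rep = pc.cross_validate(fs, SVMConfig(seed=7))

        from sklearn.model_selection import StratifiedKFold
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        Xg = StandardScaler().fit_transform(X)  # leaky global standardization
        skf = StratifiedKFold(5, shuffle=True, random_state=7)
        oof = np.empty(2 * n, int)
        for tr, te in skf.split(Xg, y):
            svc = SVC(C=1.0, kernel="rbf", gamma=0.25).fit(Xg[tr], y[tr])
            oof[te] = svc.predict(Xg[te])
        assert not np.array_equal(rep.oof_labels, oof)

    def test_too_many_folds_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            pc.cross_validate(LabeledFeatureSet(X, y), SVMConfig(n_folds=5, seed=0))


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        fs = gaussian_set([[0, 0, 0], [15, 15, 15]], sd=0.3, seed=8)
        auc = pc.roc_auc(fs, SVMConfig(seed=8))
        assert auc[0] == pytest.approx(1.0)
        assert auc["macro"] == pytest.approx(1.0)

    def test_label_independent_scores_give_half_auc(self):
        fs = gaussian_set([[0, 0, 0], [0, 0, 0]], n=1000, seed=9)
        auc = pc.roc_auc(fs, SVMConfig(seed=9))
        se = np.sqrt(1.0 / 12 / 1000)  # rank-statistic SE at n=m=1000
        assert abs(auc["macro"] - 0.5) < 4 * se


class TestStructuralFeatureRate:
    def test_threshold_variant_counts_high_rms_events(self):
        df = pd.DataFrame({"I_B": 0.7, "t_D_us": 1000.0,
                           "i_rms_nA": [0.1, 0.2, 1.5, 2.0],
                           "label": "mtDNA"})
        assert pc.structural_feature_rate(df, 0.5) == 0.5

    def test_all_fragment_input_rate_is_low(self, three_class_features):
        art = pc.train_svm(three_class_features, SVMConfig(seed=0))
        frag = pc.sample_event_features(pc.DEFAULT_CLASSES["fragment"], 1000, seed=77)
        rate = pc.structural_feature_rate(pc.build_features(frag), art)
        assert rate <= 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pc.structural_feature_rate(pd.DataFrame(columns=["i_rms_nA"]), 0.5)
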