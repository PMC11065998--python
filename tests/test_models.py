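import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from cfmm.models import (MDSEmbedder, ModelBundle, ModelInputBuilder,
                         RandomForestCV, build_model_inputs, classify_at_cutoff,
                         evaluate, mds_embed, rfe_select,
                         threshold_at_specificity, train_rf_cv)
from oracles import auc_by_pair_counting, best_cutoff_exhaustive


class TestMds:
    def test_recovers_planar_configuration(self, rng):
        X = rng.normal(size=(8, 2))
        emb = MDSEmbedder().fit(X)
        assert emb.stress_ < 1e-6
        # distances preserved (embedding is X up to isometry)
        assert np.allclose(squareform(pdist(emb.embedding_)),
                           squareform(pdist(X)), atol=1e-6)

    def test_equilateral_triangle(self):
        # 3 mutually equidistant points in 3-D embed as an equilateral triangle
        X = np.eye(3)
        emb = MDSEmbedder().fit(X)
        d = pdist(emb.embedding_)
        assert np.allclose(d, d[0], atol=1e-6)

    def test_agrees_with_independent_smacof(self, rng):
        X = rng.normal(size=(10, 6))
        emb = MDSEmbedder().fit(X)
        D = squareform(pdist(X))
        init = MDSEmbedder._classical_init(D, 2)
        _, stress = smacof(D, n_components=2, init=init, n_init=1,
                           max_iter=2000, eps=1e-14, metric=True)
        # sklearn reports sum over ordered pairs / 2 == our i<j sum
        assert emb.stress_ == pytest.approx(2 * stress / 2, abs=1e-6)

    def test_zero_variance_input(self):
        X = np.ones((5, 3))
        emb = MDSEmbedder().fit(X)
        assert np.allclose(emb.embedding_, emb.embedding_[0])
        assert emb.stress_ == 0.0

    def test_deterministic(self, rng):
        X = rng.normal(size=(12, 4))
        a = mds_embed(X, seed=0).embedding_
        b = mds_embed(X, seed=0).embedding_
        assert np.array_equal(a, b)

    def test_out_of_sample_projection(self, rng):
        X = rng.normal(size=(20, 5))
        emb = MDSEmbedder().fit(X)
        proj = emb.transform(X[:4])
        assert np.allclose(proj, emb.embedding_[:4], atol=1e-4)


class TestRandomForestCV:
    @staticmethod
    def _separable(rng, n=60):
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += 4 * y
        return X, y

    def test_separable_data_high_auc(self, rng):
        X, y = self._separable(rng)
        clf = RandomForestCV(n_trees=100, k_folds=5, seed=0).fit(X, y)
        assert clf.oof_auc_ >= 0.99
        assert np.isfinite(clf.oof_scores_).all()

    def test_permuted_labels_chance_auc(self, rng):
        X = rng.normal(size=(200, 5))
        y = np.array([0, 1] * 100)
        clf = RandomForestCV(n_trees=100, k_folds=5, seed=0).fit(X, y)
        assert 0.4 <= clf.oof_auc_ <= 0.6

    def test_same_seed_identical_scores(self, rng):
        X, y = self._separable(rng)
        a = RandomForestCV(n_trees=50, k_folds=5, seed=3).fit(X, y)
        b = RandomForestCV(n_trees=50, k_folds=5, seed=3).fit(X, y)
        assert np.array_equal(a.oof_scores_, b.oof_scores_)
        assert np.array_equal(a.folds_, b.folds_)

    def test_folds_partition_samples(self, rng):
        X, y = self._separable(rng)
        clf = RandomForestCV(n_trees=20, k_folds=5, seed=0).fit(X, y)
        assert set(clf.folds_) == set(range(5))

    def test_small_minority_class_errors(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="minority"):
            RandomForestCV(k_folds=10).fit(X, y)


class TestRfe:
    def test_recovers_informative_features(self, rng):
        n = 80
        informative = rng.normal(size=(n, 5))
        y = (informative.sum(axis=1) > 0).astype(int)
        informative += 1.5 * y[:, None]
        noise = rng.normal(size=(n, 45))
        mat = pd.DataFrame(np.hstack([informative, noise]),
                           columns=[f"inf{i}" for i in range(5)]
                           + [f"noise{i}" for i in range(45)])
        selected, curve = rfe_select(mat, y, subset_sizes=[50, 25, 10, 5],
                                     cv_folds=4, seed=0, n_trees=100, n_select=5)
        hits = [c for c in selected if c.startswith("inf")]
        assert len(hits) >= 4
        assert curve.shape[0] == 4

    def test_all_noise_flat_curve(self, rng):
        mat = pd.DataFrame(rng.normal(size=(100, 20)),
                           columns=[f"n{i}" for i in range(20)])
        y = np.array([0, 1] * 50)
        _, curve = rfe_select(mat, y, subset_sizes=[20, 10, 5], cv_folds=4,
                              seed=0, n_trees=50)
        assert (curve["auc"] - 0.5).abs().max() < 0.2

    def test_deterministic_selection(self, rng):
        mat = pd.DataFrame(rng.normal(size=(60, 12)),
                           columns=[f"f{i}" for i in range(12)])
        y = np.array([0, 1] * 30)
        s1, _ = rfe_select(mat, y, [12, 6], cv_folds=3, seed=5, n_trees=30)
        s2, _ = rfe_select(mat, y, [12, 6], cv_folds=3, seed=5, n_trees=30)
        assert s1 == s2

    def test_oversized_subset_errors(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 4)))
        with pytest.raises(ValueError):
            rfe_select(mat, np.array([0, 1] * 10), [10], n_trees=10)


class TestModelInputs:
    @staticmethod
    def _tables(rng, n=30, n_dmr=50):
        idx = [f"s{i}" for i in range(n)]
        dmr = pd.DataFrame(rng.random((n, n_dmr)), index=idx,
                           columns=[f"d{i}" for i in range(n_dmr)])
        cnv = pd.DataFrame(rng.binomial(1, 0.2, (n, 8)), index=idx,
                           columns=[f"r{i}" for i in range(8)])
        fsr = pd.DataFrame(rng.random((n, 12)), index=idx,
                           columns=[f"b{i}" for i in range(12)])
        labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
        return dmr, cnv, fsr, labels

    def test_full_mode_column_count(self, rng):
        dmr, cnv, fsr, labels = self._tables(rng)
        X, _ = build_model_inputs(dmr, labels, cnv, fsr, mode="full")
        assert X.shape[1] == 54
        tags = {c.split(":")[0] for c in X.columns}
        assert tags == {"dmr", "cnvmds", "fsrmds"}

    def test_meth_mode_column_count(self, rng):
        dmr, cnv, fsr, labels = self._tables(rng)
        X, _ = build_model_inputs(dmr, labels, mode="meth")
        assert X.shape[1] == 50

    def test_empty_cnv_matrix_errors(self, rng):
        dmr, _, fsr, labels = self._tables(rng)
        empty = pd.DataFrame(index=dmr.index)
        with pytest.raises(ValueError, match="CNV event matrix"):
            build_model_inputs(dmr, labels, empty, fsr, mode="meth_cnv")

    def test_missing_dmr_cells_imputed_with_control_median(self, rng):
        dmr, cnv, fsr, labels = self._tables(rng)
        dmr.iloc[0, 0] = np.nan
        builder = ModelInputBuilder(mode="meth").fit(dmr, labels)
        X = builder.transform(dmr)
        expect = dmr.loc[labels == 0, "d0"].median()
        assert X.iloc[0, 0] == pytest.approx(expect)

    def test_sample_mismatch_errors(self, rng):
        dmr, cnv, fsr, labels = self._tables(rng)
        builder = ModelInputBuilder(mode="meth_cnv").fit(dmr, labels, cnv_events=cnv)
        with pytest.raises(ValueError, match="align"):
            builder.transform(dmr, cnv_events=cnv.iloc[:5])


class TestThresholding:
    def test_order_statistic_cutoff(self):
        scores = np.concatenate([np.arange(1, 21) / 100.0, [0.9, 0.95]])
        labels = np.array([0] * 20 + [1] * 2)
        c = threshold_at_specificity(scores, labels, 0.95)
        # 19/20 controls below the cutoff: smallest achieving cutoff is 0.20
        ctrl = scores[labels == 0]
        assert np.mean(ctrl < c) >= 0.95
        assert c == pytest.approx(0.20)

    def test_target_one_above_max_control(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        c = threshold_at_specificity(scores, labels, 1.0)
        assert c > 0.4

    def test_target_zero_minimal_cutoff(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        c = threshold_at_specificity(scores, labels, 0.0)
        assert (classify_at_cutoff(scores, c) == 1).all()

    def test_degenerate_scores_warn(self):
        scores = np.full(10, 0.5)
        labels = np.array([0] * 5 + [1] * 5)
        with pytest.warns(UserWarning):
            c = threshold_at_specificity(scores, labels, 0.95)
        assert c > 0.5

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            target = float(rng.choice([0.0, 0.5, 0.8, 0.95, 1.0]))
            got = threshold_at_specificity(scores, labels, target)
            want = best_cutoff_exhaustive(scores, labels, target)
            ctrl = scores[labels == 0]
            assert np.mean(ctrl < got) >= target or got > ctrl.max()
            assert got == pytest.approx(want)


class TestEvaluate:
    def test_perfect_and_inverted_separation(self):
        labels = np.array([1] * 5 + [0] * 5)
        hi = np.array([0.9] * 5 + [0.1] * 5)
        assert evaluate(hi, labels, n_boot=10)["auc"] == 1.0
        assert evaluate(1 - hi, labels, n_boot=10)["auc"] == 0.0

    def test_cutoff_classification(self):
        assert classify_at_cutoff([0.50], 0.5)[0] == 1
        assert classify_at_cutoff([0.49], 0.5)[0] == 0
        assert classify_at_cutoff([0.0, 0.2], 0.0).tolist() == [1, 1]

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            scores = np.round(rng.random(20), 1)  # ties likely
            labels = np.array([1] * 10 + [0] * 10)
            got = evaluate(scores, labels, n_boot=5)["auc"]
            assert got == pytest.approx(auc_by_pair_counting(scores, labels))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            evaluate([0.5, 0.6], [1, 1])

    def test_confusion_metrics(self):
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        labels = np.array([1, 0, 1, 0])
        m = evaluate(scores, labels, cutoff=0.5, n_boot=10)
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["accuracy"] == 0.5

    @given(st.lists(st.floats(min_value=0.001, max_value=0.999), min_size=8,
                    max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, raw):
        scores = np.asarray(raw)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a = evaluate(scores, labels, n_boot=2)["auc"]
        b = evaluate(np.log(scores / (1 - scores)), labels, n_boot=2)["auc"]
        assert a == pytest.approx(b)


class TestBundle:
    def test_roundtrip_and_determinism(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)),
                         columns=[f"f{i}" for i in range(4)])
        y = np.array([0, 1] * 20)
        b1 = train_rf_cv(X, y, n_trees=30, k_folds=4, seed=7)
        b2 = train_rf_cv(X, y, n_trees=30, k_folds=4, seed=7)
        assert np.array_equal(b1.oof_scores, b2.oof_scores)
        b1.save(tmp_path / "m")
        loaded = ModelBundle.load(tmp_path / "m")
        assert loaded.feature_names == b1.feature_names
        assert np.array_equal(loaded.oof_scores, b1.oof_scores)
        assert np.array_equal(loaded.model.decision_scores(X.to_numpy()),
                              b1.model.decision_scores(X.to_numpy()))
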