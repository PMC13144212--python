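import numpy as np
import pandas as pd
import pytest
from scipy import stats

import volatilofp as v


class TestFisherRatio:
    def test_hand_example_f_equals_32(self):
        X = np.array([[1.0], [2.0], [5.0], [6.0]])
        res = v.fisher_ratio(X, ["A", "A", "B", "B"])
        assert res.f.iloc[0] == pytest.approx(32.0)

    def test_constant_feature_guarded_to_zero(self):
        X = np.array([[3.0], [3.0], [3.0], [3.0]])
        res = v.fisher_ratio(X, ["A", "A", "B", "B"])
        assert res.f.iloc[0] == 0.0

    def test_equals_anova_f_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_cls = rng.integers(2, 4)
            sizes = rng.integers(3, 7, n_cls)
            labels = np.repeat([f"c{k}" for k in range(n_cls)], sizes)
            X = rng.normal(size=(labels.size, 4))
            mine = v.fisher_ratio(X, labels).f.values
            oracle = np.array(
                [
                    stats.f_oneway(*[X[labels == c, j] for c in np.unique(labels)]).statistic
                    for j in range(4)
                ]
            )
            np.testing.assert_allclose(mine, oracle, atol=1e-9, rtol=1e-9)

    def test_class_size_validation(self):
        with pytest.raises(ValueError):
            v.fisher_ratio(np.zeros((3, 2)), ["A", "A", "B"])


class TestSelectFeatures:
    def test_strict_threshold(self):
        res = v.fisher_ratio(np.array([[1.0], [2.0], [5.0], [6.0]]), ["A", "A", "B", "B"])
        res.f.iloc[0] = 6.0
        assert v.select_features(res) == []
        res.f.iloc[0] = 6.01
        assert v.select_features(res) == [0]

    def test_zero_threshold_keeps_varying_features(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        res = v.fisher_ratio(X, ["A"] * 4 + ["B"] * 4)
        assert len(v.select_features(res, threshold=0.0)) == 5


class TestPCA:
    def test_rank_one_data_dominates_pc1(self):
        rng = np.random.default_rng(2)
        direction = rng.normal(size=10)
        X = np.outer(rng.normal(size=30), direction) + rng.normal(0, 1e-4, (30, 10))
        _, _, ev = v.pca(X, 3)
        assert ev[0] > 99.0
        assert np.all(np.diff(ev) <= 1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        scores, loadings, _ = v.pca(X, 5)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings.T, Xc, atol=1e-8)

    def test_agreement_with_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        scores, loadings, _ = v.pca(X, 4)
        from sklearn.decomposition import PCA as SkPCA

        sk = SkPCA(n_components=4).fit(X)
        for k in range(4):
            dot = abs(loadings[:, k] @ sk.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_component_count_validated(self):
        with pytest.raises(ValueError):
            v.pca(np.zeros((5, 3)), 5)


class TestPLSDA:
    def separable(self, n=20, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        X[:, 0] += np.where(y == "A", 0.0, 10.0)
        return X, y

    def test_separable_training_accuracy_one(self):
        X, y = self.separable()
        m = v.plsda_fit(X, y, n_lv=1)
        assert (v.plsda_predict(m, X) == y).all()

    def test_x_scores_orthogonal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 8))
        y = np.array(["A", "B"] * 12 + ["A"])
        m = v.plsda_fit(X, y, n_lv=3)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_agreement_with_sklearn_pls2(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 8))
        y = np.array(["A"] * 15 + ["B"] * 15)
        m = v.plsda_fit(X, y, n_lv=3)
        Y = (y[:, None] == m.classes[None, :]).astype(float)
        from sklearn.cross_decomposition import PLSRegression

        sk = PLSRegression(n_components=3, scale=False).fit(X, Y)
        mine = (X - m.x_mean) @ m.coef + m.y_mean
        np.testing.assert_allclose(mine, sk.predict(X), atol=1e-10)

    def test_lv_exceeding_rank_rejected(self):
        X, y = self.separable(n=6)
        with pytest.raises(ValueError):
            v.plsda_fit(X, y, n_lv=6)


class TestVIP:
    def test_informative_feature_has_dominant_vip(self):
        X, y = TestPLSDA().separable()
        m = v.plsda_fit(X, y, n_lv=2)
        scores = v.vip(m)
        assert scores.idxmax() == 0
        assert scores.iloc[0] > 1.5
        assert (scores.drop(index=0) < 1.0).all()

    def test_mean_square_vip_is_one(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            X = rng.normal(size=(15, 7))
            y = np.array(["A"] * 8 + ["B"] * 7)
            m = v.plsda_fit(X, y, n_lv=3)
            assert float((v.vip(m) ** 2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        y = np.array(["A"] * 5 + ["B"] * 5)
        m = v.plsda_fit(X, y, n_lv=2)
        # independent brute-force evaluation of the published formula
        p = 5
        ssy = []
        for a in range(2):
            t = m.x_scores[:, a]
            q = m.y_loadings[:, a]
            ssy.append((t @ t) * (q @ q))
        ssy = np.array(ssy)
        expected = np.zeros(p)
        for j in range(p):
            acc = 0.0
            for a in range(2):
                w = m.weights[:, a]
                acc += ssy[a] * (w[j] / np.linalg.norm(w)) ** 2
            expected[j] = np.sqrt(p * acc / ssy.sum())
        np.testing.assert_allclose(v.vip(m).values, expected, atol=1e-12)


class TestMonteCarloCV:
    def test_separable_data_perfect_accuracy(self):
        X, y = TestPLSDA().separable(n=40)
        rep = v.monte_carlo_cv(X, y, reps=20, n_lv=1, fisher_threshold=None, seed=0)
        assert rep.mean_accuracy == 1.0

    def test_stratified_holdout_counts(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        y = np.array(["A"] * 40 + ["B"] * 20)
        rep = v.monte_carlo_cv(X, y, holdout=0.10, reps=30, fisher_threshold=None, n_lv=2, seed=1)
        # every rep holds out round(40*0.1)=4 A's and round(20*0.1)=2 B's
        assert rep.confusion.to_numpy().sum() == 30 * 6
        assert rep.confusion.loc["A"].sum() == 30 * 4
        assert rep.confusion.loc["B"].sum() == 30 * 2

    def test_permutation_null_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 10))
        y = rng.permutation(np.array(["A", "B"] * 100))
        rep = v.monte_carlo_cv(X, y, holdout=0.10, reps=40, n_lv=3, fisher_threshold=None, seed=2)
        assert abs(rep.mean_accuracy - 0.5) < 0.08

    def test_deterministic_under_seed(self):
        X, y = TestPLSDA().separable(n=30, seed=12)
        X = X + np.random.default_rng(0).normal(0, 5, X.shape)  # make it non-trivial
        r1 = v.monte_carlo_cv(X, y, reps=10, seed=3)
        r2 = v.monte_carlo_cv(X, y, reps=10, seed=3)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        assert r1.selected_per_rep == r2.selected_per_rep

    def test_selection_recomputed_per_split_without_leakage(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        y = np.array(["A"] * 20 + ["B"] * 20)
        X.loc[y == "B", 0] += 3.0
        rep = v.monte_carlo_cv(X, y, reps=15, n_lv=1, fisher_threshold=6.0, seed=4)
        # the informative feature is selected from calibration data in each rep
        assert all(0 in feats for feats in rep.selected_per_rep)

    def test_holdout_validation(self):
        X, y = TestPLSDA().separable()
        with pytest.raises(ValueError):
            v.monte_carlo_cv(X, y, holdout=0.8)


class TestChordData:
    def test_strict_two_percent_rule(self):
        percent = pd.DataFrame(
            {"f1": [2.5, 2.5], "f2": [2.0, 2.0], "f3": [1.9, 1.9], "f4": [93.6, 93.6]},
            index=["s1", "s2"],
        )
        edges = v.chord_data(percent, groups=["G", "G"])
        feats = set(edges.feature)
        assert "f1" in feats and "f4" in feats
        assert "f2" not in feats and "f3" not in feats

    def test_group_means_reported(self):
        percent = pd.DataFrame({"f1": [4.0, 2.0], "f2": [96.0, 98.0]}, index=["s1", "s2"])
        edges = v.chord_data(percent, groups=["G1", "G2"])
        g1 = edges[(edges.group == "G1") & (edges.feature == "f1")]
        assert g1.mean_percent.iloc[0] == pytest.approx(4.0)
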