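"""RF tuning/importance workflow, SVM and PLS-DA behavior, serialization."""

import numpy as np
import pytest

import ftirclass as fc
from ftirclass.core import SpectraError
from ftirclass.models import default_mtry_grid

SEED = 11


def informative_fixture(n=120, p=20, j=7, seed=0):
    """Only variable j carries class signal; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X[y == "A", j] += 3.0
    return X, y, j


class TestTuneNtree:
    def test_single_value_grid(self, easy_vf_split):
        d = easy_vf_split
        best, table = fc.tune_ntree(
            d["Xcal"], d["ycal"], fc.RFConfig(n_tree_grid=(300,), seed=SEED))
        assert best == 300
        assert len(table) == 1

    def test_winner_minimizes_oob_error(self, easy_vf_split):
        d = easy_vf_split
        cfg = fc.RFConfig(n_tree_grid=(50, 100, 200), seed=SEED)
        best, table = fc.tune_ntree(d["Xcal"], d["ycal"], cfg)
        winner = table[table.n_tree == best]["oob_error"].iloc[0]
        assert (winner <= table["oob_error"] + 1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(SpectraError):
            fc.tune_ntree(np.ones((10, 3)), ["A"] * 10)

    def test_oob_error_stabilizes_with_ensemble_size(self):
        # ensemble averaging: OOB error at 1000 trees ~ error at 500
        X, y, _ = informative_fixture(n=80, p=15, seed=3)
        errs = {500: [], 1000: []}
        for seed in range(10):
            for nt in errs:
                _, t = fc.tune_ntree(X, y, fc.RFConfig(n_tree_grid=(nt,),
                                                       seed=seed))
                errs[nt].append(float(t["oob_error"].iloc[0]))
        diff = abs(np.mean(errs[1000]) - np.mean(errs[500]))
        assert diff <= 3 * max(np.std(errs[500]), 1e-3)


class TestTuneMtry:
    def test_default_grid_centering(self):
        grid = default_mtry_grid(100)  # floor(sqrt(100)) = 10
        assert len(grid) == 8
        assert 10 in grid
        assert all(b - a == 2 for a, b in zip(grid, grid[1:]))

    def test_explicit_single_value(self, easy_vf_split):
        d = easy_vf_split
        best, table = fc.tune_mtry(d["Xcal"], d["ycal"], n_tree=100,
                                   grid=(5,), seed=SEED)
        assert best == 5 and len(table) == 1

    def test_winner_minimizes_oob_error(self, easy_vf_split):
        d = easy_vf_split
        best, table = fc.tune_mtry(d["Xcal"], d["ycal"], n_tree=100,
                                   grid=(5, 15, 29), seed=SEED)
        winner = table[table.m_try == best]["oob_error"].iloc[0]
        assert (winner <= table["oob_error"] + 1e-12).all()

    def test_grid_value_above_p_rejected(self):
        X, y, _ = informative_fixture(n=40, p=10)
        with pytest.raises(SpectraError):
            fc.tune_mtry(X, y, n_tree=50, grid=(11,))


class TestImportance:
    def test_single_informative_variable_ranks_first(self):
        X, y, j = informative_fixture(seed=1)
        model = fc.fit_rf(X, y, n_tree=200, seed=SEED)
        imp = fc.rf_importance(model, X, y)
        assert imp.shape == (X.shape[1],)
        assert np.argmax(imp) == j
        assert imp[j] == 1.0
        noise = np.delete(imp, j)
        assert np.median(np.abs(noise)) < 0.05

    def test_raw_scores_exposed(self):
        X, y, j = informative_fixture(seed=2)
        model = fc.fit_rf(X, y, n_tree=100, seed=SEED)
        fc.rf_importance(model, X, y)
        assert model.importance_raw is not None
        assert np.argmax(model.importance_raw) == j


class TestSelectByVip:
    def test_cutoff_zero_keeps_all(self):
        imp = np.array([0.0, 0.5, 1.0, 0.2])
        assert fc.select_by_vip(imp, 0.0).tolist() == [0, 1, 2, 3]

    def test_cutoff_one_pads_to_two(self):
        imp = np.array([0.0, 0.5, 1.0, 0.2])
        with pytest.warns(UserWarning):
            keep = fc.select_by_vip(imp, 1.0)
        assert keep.tolist() == [1, 2]

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        imp = rng.uniform(0, 1, 50)
        imp /= imp.max()
        sizes = [fc.select_by_vip(imp, c).size
                 for c in (0.0, 0.1, 0.3, 0.6, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestRandomForest:
    def test_easy_fixture_validation_accuracy(self, easy_vf_split):
        d = easy_vf_split
        model = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=300, seed=SEED)
        labels, _ = fc.predict(model, d["Xval"])
        assert np.mean(labels.astype(str) == d["yval"]) >= 0.95

    def test_same_seed_identical_predictions(self, easy_vf_split):
        d = easy_vf_split
        a = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=50, seed=3)
        b = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=50, seed=3)
        la, sa = fc.predict(a, d["Xval"])
        lb, sb = fc.predict(b, d["Xval"])
        np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(sa, sb)

    def test_oob_error_tracks_validation_error(self, easy_vf_split):
        d = easy_vf_split
        gaps = []
        for seed in range(5):
            m = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=200, seed=seed)
            labels, _ = fc.predict(m, d["Xval"])
            val_err = float(np.mean(labels.astype(str) != d["yval"]))
            gaps.append(abs(m.fitted_state.oob_error() - val_err))
        assert np.median(gaps) <= 0.1

    def test_column_mismatch_rejected(self, easy_vf_split):
        d = easy_vf_split
        m = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=20, seed=1)
        with pytest.raises(SpectraError, match="851"):
            fc.predict(m, d["Xval"][:, :100])


class TestSvm:
    def test_separated_clouds_are_perfectly_classified(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)),
                       rng.normal(5, 0.3, (30, 2))])
        y = np.array(["A"] * 30 + ["B"] * 30)
        m = fc.fit_svm_rbf(X, y, seed=SEED)
        labels, scores = fc.predict(m, X)
        assert np.mean(labels.astype(str) == y) == 1.0
        assert scores.min() >= 0 and scores.max() <= 1

    def test_tiny_gamma_degrades_to_near_linear_on_xor(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
        X = np.vstack([c + rng.normal(0, 0.05, (20, 2)) for c in centers])
        y = np.array(["A"] * 40 + ["B"] * 40)
        m = fc.fit_svm_rbf(X, y, cfg=fc.SVMConfig(gamma=2.0 ** -10, cost=1.0))
        labels, _ = fc.predict(m, X)
        assert np.mean(labels.astype(str) == y) <= 0.75

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = np.array(["A", "B"] * 20)
        a = fc.fit_svm_rbf(X, y, seed=7)
        b = fc.fit_svm_rbf(X, y, seed=7)
        assert a.tuned_params == b.tuned_params
        np.testing.assert_array_equal(fc.predict(a, X)[1],
                                      fc.predict(b, X)[1])

    def test_invalid_config(self):
        with pytest.raises(SpectraError):
            fc.SVMConfig(gamma=-1.0)


class TestPlsdaOutliers:
    def test_flag_rate_matches_chi2_law(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 5))
        keep = fc.plsda_outlier_removal(X, fc.PLSDAConfig(
            outlier_pca_variance=0.95, outlier_chi2_quantile=0.975))
        flagged = 200 - keep.size
        # binomial(200, 0.025) central 99% interval
        assert 0 <= flagged <= 12

    def test_displaced_sample_is_flagged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 8))
        X[17] += 10.0 * X.std(axis=0)
        keep = fc.plsda_outlier_removal(X)
        assert 17 not in keep

    def test_quantile_one_flags_nothing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        keep = fc.plsda_outlier_removal(
            X, fc.PLSDAConfig(outlier_chi2_quantile=1.0))
        assert keep.size == 30


class TestPlsda:
    def test_easy_fixture_accuracy(self, easy_vf_split):
        d = easy_vf_split
        keep = fc.plsda_outlier_removal(d["Xcal"])
        m = fc.fit_plsda(d["Xcal"][keep], d["ycal"][keep], seed=SEED)
        labels, scores = fc.predict(m, d["Xval"])
        assert np.mean(labels.astype(str) == d["yval"]) >= 0.90
        assert np.isfinite(scores).all()
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_one_component_matches_lda_on_single_direction_data(self):
        # one discriminant direction: PLS1 with 1 component should agree
        # with Fisher LDA sign predictions almost everywhere
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(12)
        n = 100
        y = np.array(["A"] * n + ["B"] * n)
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        X = rng.normal(size=(2 * n, 6)) * 0.5
        X[:n] += 1.5 * direction
        m = fc.fit_plsda(X, y, fc.PLSDAConfig(n_components=1))
        labels, _ = fc.predict(m, X)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        agree = np.mean(labels.astype(str) == lda.predict(X))
        assert agree >= 0.95

    def test_component_cap_warns_and_truncates(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 4))
        y = np.array(["A", "B"] * 6)
        with pytest.warns(UserWarning, match="truncated"):
            m = fc.fit_plsda(X, y, fc.PLSDAConfig(n_components=9))
        assert m.tuned_params["n_components"] <= 4


class TestSerialization:
    @pytest.mark.parametrize("kind", ["rf", "svm", "plsda"])
    def test_roundtrip_predictions_bit_identical(self, kind, tmp_path,
                                                 easy_vf_split):
        d = easy_vf_split
        if kind == "rf":
            m = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=30, seed=1)
        elif kind == "svm":
            m = fc.fit_svm_rbf(d["Xcal"], d["ycal"],
                               cfg=fc.SVMConfig(gamma=0.01, cost=1.0))
        else:
            m = fc.fit_plsda(d["Xcal"], d["ycal"],
                             fc.PLSDAConfig(n_components=2))
        m.save(tmp_path / kind)
        back = fc.TrainedModel.load(tmp_path / kind)
        l0, s0 = fc.predict(m, d["Xval"])
        l1, s1 = fc.predict(back, d["Xval"])
        np.testing.assert_array_equal(l0, l1)
        np.testing.assert_array_equal(s0, s1)

    def test_duplicated_row_gets_identical_prediction(self, easy_vf_split):
        d = easy_vf_split
        m = fc.fit_rf(d["Xcal"], d["ycal"], n_tree=30, seed=1)
        X2 = np.vstack([d["Xval"][0], d["Xval"][0]])
        labels, scores = fc.predict(m, X2)
        assert labels[0] == labels[1]
        assert scores[0] == scores[1]
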