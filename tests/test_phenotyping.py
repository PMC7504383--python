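"""PERMANOVA, PCoA and PLS-DA classification."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from phytospec import phenotyping as ph
from phytospec import synthetic as syn


class TestPermanova:
    def test_univariate_equals_anova_f(self):
        vals = np.array([1.0, 2, 3, 2, 3, 4, 6, 7, 8])
        grp = np.repeat(["a", "b", "c"], 3)
        res = ph.permanova(vals.reshape(-1, 1), grp, n_permutations=99, seed=0)
        f_ref, _ = sps.f_oneway(vals[:3], vals[3:6], vals[6:])
        assert res.pseudo_f == pytest.approx(f_ref, abs=1e-8)

    def test_ss_decomposition_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        grp = np.repeat(["a", "b"], 10)
        res = ph.permanova(X, grp, n_permutations=99, seed=0)
        assert res.ss_total == pytest.approx(
            res.ss_among + res.ss_within, rel=1e-8
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        grp = np.repeat(["a", "b", "c"], 5)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = ph.permanova(X, grp, n_permutations=9, seed=0)
        b = ph.permanova(X @ Q, grp, n_permutations=9, seed=0)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-8)

    def test_identical_groups_no_among_variance(self):
        block = np.arange(12.0).reshape(4, 3)
        X = np.vstack([block, block])
        grp = np.repeat(["a", "b"], 4)
        res = ph.permanova(X, grp, n_permutations=9, seed=0)
        assert res.ss_among == pytest.approx(0.0, abs=1e-8)

    def test_singleton_group_rejected(self):
        with pytest.raises(ph.PhenotypingError, match="singleton"):
            ph.permanova(np.eye(3), ["a", "a", "b"], n_permutations=9)

    def test_p_value_never_zero(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 10])
        grp = np.repeat(["a", "b"], 5)
        res = ph.permanova(X, grp, n_permutations=99, seed=0)
        assert 0 < res.p_value <= 1


class TestPcoa:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pca_on_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        res = ph.pcoa(X=X)
        Xc = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        pca_scores = U * S
        for k in range(4):
            a, b = res.scores[:, k], pca_scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_scores_reproduce_distances(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(X))
        res = ph.pcoa(D=D)
        keep = res.eigenvalues > 1e-10
        S = res.scores[:, keep]
        D2 = squareform(pdist(S))
        np.testing.assert_allclose(D2, D, atol=1e-6)

    def test_collinear_points_one_axis(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = ph.pcoa(D=D)
        assert (res.eigenvalues > 1e-10).sum() == 1

    def test_zero_distances(self):
        res = ph.pcoa(D=np.zeros((4, 4)))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1], [2, 0]])
        with pytest.raises(ph.PhenotypingError, match="symmetric"):
            ph.pcoa(D=D)

    def test_matches_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        D = squareform(pdist(X))
        mine = ph.pcoa(D=D)
        import skbio
        ref = skbio_ord.pcoa(skbio.DistanceMatrix(D))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues)[::-1][:5],
            np.asarray(ref.eigvals)[:5],
            atol=1e-6,
        )


class TestPlsda:
    def test_separable_blobs_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0, 0.1, (10, 5)),
            rng.normal(3, 0.1, (10, 5)),
        ])
        labels = np.repeat(["a", "b"], 10)
        pred = ph.plsda_fit_predict(X, labels, X, 2)
        assert (pred == labels).all()

    def test_calibration_row_recovers_class(self):
        sset, labels = syn.separable_class_spectra(8, seed=1)
        X = sset.data.to_numpy()
        pred = ph.plsda_fit_predict(X, labels, X[5:6], 4)
        assert pred[0] == labels[5]

    def test_single_component_labels_in_class_set(self):
        sset, labels = syn.separable_class_spectra(4, seed=2)
        X = sset.data.to_numpy()
        pred = ph.plsda_fit_predict(X[:9], labels[:9], X[9:], 1)
        assert set(pred) <= set(labels)


class TestCohenKappa:
    def test_diagonal_is_one(self):
        assert ph.cohen_kappa(np.diag([5, 3, 2])) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert ph.cohen_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert ph.cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_expected_table_is_zero(self):
        # outer product of margins: observed agreement equals chance
        row = np.array([30.0, 20.0])
        col = np.array([25.0, 25.0])
        cm = np.outer(row, col) / 50.0
        assert ph.cohen_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cell(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ph.cohen_kappa([[10, 0], [0, 0]]) == 0.0


class TestPlsdaGrid:
    def test_separable_classes_high_kappa(self):
        sset, labels = syn.separable_class_spectra(8, seed=0)
        X = sset.data.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = ph.plsda_grid(X, labels, component_grid=(2, 4),
                                 n_iter=30, seed=0)
        assert grid.best.kappa_mean >= 0.9
        assert grid.best.accuracy_mean >= max(
            np.mean(labels == c) for c in np.unique(labels)
        )

    def test_reproducible_under_seed(self):
        sset, labels = syn.separable_class_spectra(6, seed=3)
        X = sset.data.to_numpy()
        kw = dict(ratios=(0.7,), component_grid=(2, 3), n_iter=10, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ph.plsda_grid(X, labels, **kw)
            b = ph.plsda_grid(X, labels, **kw)
        assert a.grid.equals(b.grid)
        assert (a.best.cal_fraction, a.best.n_components) == (
            b.best.cal_fraction, b.best.n_components
        )

    def test_oversized_components_skipped(self):
        sset, labels = syn.separable_class_spectra(3, seed=4)
        X = sset.data.to_numpy()
        with pytest.warns(UserWarning, match="skipping"):
            grid = ph.plsda_grid(X, labels, ratios=(0.5,),
                                 component_grid=(2, 40), n_iter=5, seed=0)
        assert set(grid.grid.n_components) == {2}

    def test_confusion_rows_sum_to_class_counts(self):
        sset, labels = syn.separable_class_spectra(6, seed=6)
        X = sset.data.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = ph.plsda_grid(X, labels, ratios=(0.5,),
                                 component_grid=(3,), n_iter=10, seed=0)
        # 0.5 split of 6 -> 3 validation per class per iteration
        np.testing.assert_allclose(
            grid.best.confusion.sum(axis=1), 3 * 10
        )
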