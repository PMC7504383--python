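"""NIPALS PLS1: oracles, PRESS, component selection, VIP, coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytospec import pls
from phytospec import synthetic as syn


def random_instance(seed, n=30, p=5, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_single_predictor_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 2.0 + 3.0 * x + rng.normal(size=40)
        m = pls.fit_pls(x[:, None], y, 1)
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert m.coefficients_raw[0] == pytest.approx(slope, rel=1e-10)
        assert m.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_equals_ols(self, seed):
        X, y = random_instance(seed)
        m = pls.fit_pls(X, y, 5)
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )[0]
        np.testing.assert_allclose(m.coefficients_raw, beta[1:], rtol=1e-6)

    def test_scores_orthogonal(self):
        X, y = random_instance(3, n=50, p=20)
        m = pls.fit_pls(X, y, 10)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * norms.max() ** 2

    def test_null_response_low_r2(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 30))
        y = rng.permutation(X @ rng.normal(size=30))
        m = pls.fit_pls(X, y, 1)
        yhat = pls.predict(m, X)
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        assert r2 < 0.2

    def test_nan_rejected(self):
        X, y = random_instance(0)
        X[0, 0] = np.nan
        with pytest.raises(pls.PLSError, match="NaN"):
            pls.fit_pls(X, y, 2)

    def test_rank_collapse_reduces_components(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 2))
        X = base @ rng.normal(size=(2, 6))  # rank 2
        y = X @ rng.normal(size=6)
        with pytest.warns(UserWarning, match="rank|degenerate"):
            m = pls.fit_pls(X, y, 5, scale=False)
        assert m.n_components <= 3

    def test_json_roundtrip(self):
        X, y = random_instance(2)
        m = pls.fit_pls(X, y, 3, wavelengths=np.arange(5))
        back = pls.PLSModel.from_json(m.to_json())
        np.testing.assert_allclose(back.coefficients_raw, m.coefficients_raw)
        np.testing.assert_allclose(pls.predict(back, X), pls.predict(m, X))


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        X, y = random_instance(4)
        m = pls.fit_pls(X, y, 3)
        assert pls.predict(m, X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), rel=1e-8
        )

    def test_duplicated_row_duplicated_prediction(self):
        X, y = random_instance(5)
        m = pls.fit_pls(X, y, 3)
        two = pls.predict(m, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_grid_mismatch_rejected(self):
        X, y = random_instance(6)
        m = pls.fit_pls(X, y, 2, wavelengths=np.arange(5))
        with pytest.raises(pls.PLSError, match="wavelength"):
            pls.predict(m, X, wavelengths=np.arange(5) + 1)
        with pytest.raises(pls.PLSError, match="mismatch"):
            pls.predict(m, X[:, :4])

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_equivariance_in_y(self, c):
        """Shifting y by c shifts every prediction by c."""
        X, y = random_instance(11)
        m0 = pls.fit_pls(X, y, 3)
        m1 = pls.fit_pls(X, y + c, 3)
        np.testing.assert_allclose(
            pls.predict(m1, X), pls.predict(m0, X) + c, atol=1e-8
        )

    def test_component_path_consistent(self):
        X, y = random_instance(12)
        m = pls.fit_pls(X, y, 4)
        path = pls.predict_components(m, X)
        np.testing.assert_allclose(path[:, -1], pls.predict(m, X), atol=1e-10)


class TestLooPress:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        curve = pls.loo_press(X, y, 3)
        assert curve.press[2] < 1e-10

    def test_matches_brute_force_enumeration(self):
        X, y = random_instance(9, n=5, p=2, noise=0.5)
        curve = pls.loo_press(X, y, 2)
        manual = np.zeros(2)
        for i in range(5):
            keep = [j for j in range(5) if j != i]
            m = pls.fit_pls(X[keep], y[keep], 2)
            manual += (y[i] - pls.predict_components(m, X[i:i + 1])[0]) ** 2
        np.testing.assert_allclose(curve.press, manual, rtol=1e-10)

    def test_pure_noise_flat_curve(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 10))
        y = rng.normal(size=100)
        curve = pls.loo_press(X, y, 8)
        assert curve.press.min() > curve.press[0] / 2.0

    def test_too_many_components_truncated(self):
        X, y = random_instance(13, n=6, p=10)
        with pytest.warns(UserWarning, match="reduced"):
            curve = pls.loo_press(X, y, 9)
        assert curve.components[-1] == 4  # n - 2


class TestSelectNcomp:
    @pytest.mark.parametrize(
        "press,rule,expected",
        [
            ([10, 8, 6, 4], "min", 4),          # monotone decreasing
            ([5, 5, 5, 5], "onesigma", 1),      # flat: tie -> smallest
            ([5, 5, 5, 5], "min", 1),
            ([10, 4, 3.9, 3.95], "onesigma", 2),  # 4 <= 3.9 * 1.05
            ([10, 4.2, 3.9, 3.95], "onesigma", 3),
        ],
    )
    def test_rules(self, press, rule, expected):
        curve = pls.PressCurve(
            components=np.arange(1, len(press) + 1),
            press=np.asarray(press, dtype=float),
        )
        assert pls.select_ncomp(curve, rule=rule) == expected


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        # A single component with equal weights spreads importance evenly
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        X = np.tile(t[:, None], (1, 4)) + 1e-9 * rng.normal(size=(40, 4))
        m = pls.fit_pls(X, t, 1)
        np.testing.assert_allclose(pls.vip(m), 1.0, atol=1e-3)

    def test_normalisation(self):
        for seed in range(5):
            X, y = random_instance(seed, n=40, p=12)
            m = pls.fit_pls(X, y, 5)
            v = pls.vip(m)
            assert np.sum(v ** 2) == pytest.approx(12, abs=1e-8)

    def test_single_informative_band_localised(self):
        wl, X, y = syn.single_band_spectra(60, seed=0)
        m = pls.fit_pls(X, y, 5)
        assert 660 <= wl[np.argmax(pls.vip(m))] <= 700


class TestStandardizedCoefficients:
    def test_scale_invariance(self):
        X, y = random_instance(14)
        m0 = pls.fit_pls(X, y, 3)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        m1 = pls.fit_pls(X2, y, 3)
        np.testing.assert_allclose(
            pls.standardized_coefficients(m0),
            pls.standardized_coefficients(m1),
            atol=1e-8,
        )

    def test_single_predictor_equals_pearson_r(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        m = pls.fit_pls(x[:, None], y, 1)
        r = np.corrcoef(x, y)[0, 1]
        assert pls.standardized_coefficients(m)[0] == pytest.approx(r, rel=1e-8)

    def test_null_response_near_zero(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(300, 5))
        y = rng.normal(size=300)
        m = pls.fit_pls(X, y, 2)
        assert np.abs(pls.standardized_coefficients(m)).max() < 0.25


class TestAgainstSklearn:
    """Independent cross-check against an established PLS implementation."""

    def test_predictions_match_sklearn(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_instance(20, n=40, p=15)
        for a in (1, 3, 5):
            mine = pls.fit_pls(X, y, a, scale=True)
            ref = sklearn_pls.PLSRegression(n_components=a, scale=True).fit(
                X, y
            )
            np.testing.assert_allclose(
                pls.predict(mine, X), ref.predict(X).ravel(), atol=1e-8
            )
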