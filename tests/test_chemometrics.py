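"""PLS1 calibration, splitting, cross-validation and the metric suite."""

import numpy as np
import pandas as pd
import pytest

import cocoahsi as chs
from cocoahsi.chemometrics import CVCurve, fit_pls


def brute_force_loo_curve(X, y, max_lv):
    """Independent oracle: explicit leave-one-out refit loop using only
    fit_pls on each fold at each LV count."""
    n = len(y)
    sq = np.zeros(max_lv)
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, max_lv + 1):
            m = fit_pls(X[keep], y[keep], a)
            sq[a - 1] += (m.predict(X[i:i + 1])[0] - y[i]) ** 2
    return np.sqrt(sq / n)


@pytest.fixture(scope="module")
def panel():
    return chs.sample_reference_panel(17, 10, seed=0)


class TestSplitByBatch:
    def test_published_design_counts(self, panel):
        split = chs.split_by_batch(panel, fraction=0.7, seed=1)
        roles = split.table.role.value_counts()
        assert roles["calibration"] == 119 and roles["validation"] == 51
        # two sides per bean: 238 calibration, 102 validation spectra
        assert 2 * roles["calibration"] == 238
        assert 2 * roles["validation"] == 102

    def test_exact_per_batch_proportions(self, panel):
        split = chs.split_by_batch(panel, fraction=0.7, seed=2)
        per_batch = split.table.groupby("batch_id").role.value_counts().unstack()
        assert (per_batch["calibration"] == 7).all()
        assert (per_batch["validation"] == 3).all()

    def test_no_bean_in_both_roles(self, panel):
        split = chs.split_by_batch(panel, fraction=0.7, seed=3)
        assert not split.table.duplicated(["batch_id", "bean_id"]).any()

    def test_degenerate_fractions_rejected(self, panel):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                chs.split_by_batch(panel, fraction=bad)

    def test_deterministic_given_seed(self, panel):
        a = chs.split_by_batch(panel, seed=7).table
        b = chs.split_by_batch(panel, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_sides_inherit_bean_role(self, panel):
        split = chs.split_by_batch(panel, seed=0)
        ids = pd.DataFrame({
            "batch_id": [1, 1], "bean_id": [1, 1], "side": ["A", "B"],
        })
        roles = split.roles_for(ids)
        assert roles[0] == roles[1]


class TestFitPLS:
    def test_rank_one_noiseless_single_factor(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = 2.0 * t + 1.0
        model = fit_pls(X, y, 1)
        pred = model.predict(X)
        assert np.sqrt(np.mean((pred - y) ** 2)) <= 1e-8
        assert chs.evaluate(y, pred).r2 == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        pred_ols = Xc @ b_ols + y.mean()
        assert np.max(np.abs(model.predict(X) - pred_ols)) <= 1e-8

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        model = fit_pls(X, y, 5)
        Xd = X - model.x_mean
        T = np.empty((25, 5))
        for a in range(5):
            T[:, a] = Xd @ model.weights[:, a]
            Xd -= np.outer(T[:, a], model.x_loadings[:, a])
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off) / np.outer(norms, norms)) <= 1e-8

    def test_b_reproduces_score_recursion(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=30)
        model = fit_pls(X, y, 4)
        X_new = rng.normal(size=(7, 10))
        assert np.max(np.abs(model.predict(X_new)
                             - model.predict_via_scores(X_new))) <= 1e-8

    def test_excess_components_rejected_with_rank(self):
        rng = np.random.default_rng(4)
        X = np.outer(rng.normal(size=10), rng.normal(size=6))  # rank 1
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank 1"):
            fit_pls(X, y, 3)

    def test_constant_y_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="variance"):
            fit_pls(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_matches_reference_implementation(self):
        # independent cross-check against scikit-learn's PLS
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15) + 0.3 * rng.normal(size=40)
        for lv in (1, 4, 8):
            ours = fit_pls(X, y, lv).predict(X)
            theirs = PLSRegression(n_components=lv, scale=False).fit(X, y)
            assert np.max(np.abs(ours - theirs.predict(X).ravel())) <= 1e-8

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = fit_pls(X, y, 3, wavelengths=np.linspace(1000, 1500, 6),
                        constituent="TP")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = chs.PLSModel.from_json(path)
        np.testing.assert_allclose(back.b, model.b)
        assert back.n_lv == 3 and back.constituent == "TP"
        np.testing.assert_allclose(back.predict(X), model.predict(X))


class TestCrossValidate:
    def test_singleton_groups_match_brute_force_loo(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 6))
        y = X @ rng.normal(size=6) + 0.2 * rng.normal(size=12)
        curve = chs.cross_validate(X, y, np.arange(12), max_lv=4)
        expected = brute_force_loo_curve(X, y, 4)
        assert np.max(np.abs(curve.rmsecv - expected)) <= 1e-8

    def test_duplicated_rows_same_group_identical_curve(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        base = chs.cross_validate(X, y, np.arange(10), max_lv=3)
        X2 = np.repeat(X, 2, axis=0)
        y2 = np.repeat(y, 2)
        g2 = np.repeat(np.arange(10), 2)
        doubled = chs.cross_validate(X2, y2, g2, max_lv=3)
        np.testing.assert_allclose(doubled.rmsecv, base.rmsecv, atol=1e-10)

    def test_noiseless_rank_one_flat_curve(self):
        rng = np.random.default_rng(12)
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=5))
        y = 3.0 * t
        curve = chs.cross_validate(X, y, np.arange(10), max_lv=4)
        assert curve.rmsecv[0] <= 1e-8
        assert np.all(curve.rmsecv <= curve.rmsecv[0] + 1e-8)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="group"):
            chs.cross_validate(rng.normal(size=(6, 3)), rng.normal(size=6),
                               np.zeros(6), max_lv=2)


class TestSelectLV:
    @pytest.mark.parametrize("curve, expected", [
        ([0.50, 0.30, 0.31], 2),
        ([0.4, 0.3, 0.3], 2),          # tie broken toward fewer LVs
        (list(np.linspace(1.5, 0.1, 15)), 15),
    ])
    def test_selection_rule(self, curve, expected):
        assert chs.select_lv(CVCurve(np.array(curve))) == expected


class TestEvaluate:
    def test_published_rpd_arithmetic(self):
        # Table-printed SDs and RMSEs reproduce the printed RPDs
        assert round(chs.rpd(114.9, 60.04), 2) == 1.91
        assert round(chs.rpd(60.5, 34.13), 2) == 1.77

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = chs.evaluate(y, y)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0
        assert m.slope == pytest.approx(1.0)
        assert m.bias == 0.0
        assert m.rpd is None
        with pytest.raises(ValueError, match="zero RMSE"):
            chs.evaluate(y, y, sd_ref=1.0)

    def test_rpd_rmse_consistency(self):
        rng = np.random.default_rng(14)
        y = rng.normal(100, 20, size=50)
        pred = y + rng.normal(0, 5, size=50)
        sd = y.std(ddof=1)
        m = chs.evaluate(y, pred, sd_ref=sd)
        assert m.rpd * m.rmse == pytest.approx(sd, rel=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            chs.evaluate(np.ones(5), np.arange(5.0))

    def test_explained_variance_variant_differs_under_bias(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = y + 10.0  # perfectly correlated, hugely biased
        assert chs.evaluate(y, pred).r2 == pytest.approx(1.0)
        assert chs.r2_explained_variance(y, pred) < 0


class TestPearson:
    def test_identity(self):
        x = np.arange(10.0)
        r, p, flag = chs.pearson(x, x)
        assert r == pytest.approx(1.0)
        assert flag == "highly_significant"

    def test_constructed_orthogonal(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function: r = 0
        r, p, flag = chs.pearson(x, y)
        assert abs(r) < 1e-12
        assert flag == "ns"

    def test_hand_formula_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        r, _, _ = chs.pearson(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)


class TestCoefficientPeaks:
    def _model_with_b(self, b, wavelengths):
        rng = np.random.default_rng(15)
        n = len(b)
        model = fit_pls(rng.normal(size=(10, n)), rng.normal(size=10), 1,
                        wavelengths=wavelengths)
        model.b = np.asarray(b, dtype=float)
        return model

    def test_single_spike(self):
        wl = np.linspace(1000, 1500, 11)
        b = np.zeros(11)
        b[4] = 2.0
        model = self._model_with_b(b, wl)
        assert chs.coefficient_peaks(model, 1) == [wl[4]]

    def test_all_zero_warns_and_returns_empty(self):
        wl = np.linspace(1000, 1500, 8)
        model = self._model_with_b(np.zeros(8), wl)
        with pytest.warns(UserWarning, match="zero"):
            assert chs.coefficient_peaks(model, 3) == []

    def test_descending_magnitude_and_truncation_warning(self):
        wl = np.linspace(1000, 1500, 9)
        b = np.array([0.0, 1.0, 0.0, -3.0, 0.0, 2.0, 0.0, 0.5, 0.0])
        model = self._model_with_b(b, wl)
        assert chs.coefficient_peaks(model, 3) == [wl[3], wl[5], wl[1]]
        with pytest.warns(UserWarning, match="extrema"):
            got = chs.coefficient_peaks(model, 50)
        assert got[:3] == [wl[3], wl[5], wl[1]]
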