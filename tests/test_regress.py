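"""PLS1 regression, CV component selection, VIP and sex-residual analysis."""

import numpy as np
import pandas as pd
import pytest

from torsoshape import regress
from torsoshape.regress import (fit_plsr, residuals_on_sex, select_ncomponents,
                                variance_decomposition, vip, waist_girth_sweep)


def two_direction_data(n=200, p=10, noise=0.10, seed=0):
    """Response built from two orthogonal latent directions of X.

    The factors have unequal variances so the first PLS component (the
    covariance-maximising direction) cannot capture both at once.
    """
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.normal(size=(p, 2)))
    t1 = rng.normal(size=n) * 2.0
    t2 = rng.normal(size=n)
    X = np.outer(t1, basis[:, 0]) + np.outer(t2, basis[:, 1]) \
        + 0.3 * rng.normal(size=(n, p))
    signal = t1 + 2.0 * t2
    y = signal + noise * signal.std() * rng.normal(size=n)
    return X, y


class TestFitPLSR:
    def test_exact_linear_fit_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 4.0
        model = fit_plsr(X, y, n_components=5)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_predictor_equals_ols_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 1))
        y = 2.5 * x[:, 0] + rng.normal(size=80)
        model = fit_plsr(x, y, n_components=1)
        slope = np.polyfit(x[:, 0], y, 1)[0]
        assert model.coef[0] == pytest.approx(slope, abs=1e-9)

    def test_full_components_equal_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=100) * 0.5
        model = fit_plsr(X, y, n_components=6)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        assert np.allclose(model.coef, beta, atol=1e-8)

    def test_matches_sklearn_reference(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(70, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=70)
        for a in (1, 2, 4):
            ours = fit_plsr(X, y, n_components=a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_null_response_low_r2(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 34))
        y = rng.normal(size=2000)
        model = fit_plsr(X, y, n_components=1)
        assert model.r2 < 0.05

    def test_rank_exceeded_raises(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=40)
        X = np.column_stack([x1, 2.0 * x1])  # rank 1
        y = x1 + 0.01 * rng.normal(size=40)
        with pytest.raises(ValueError, match="rank"):
            fit_plsr(X, y, n_components=2)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            fit_plsr(np.ones((4, 3)), np.ones(4), n_components=3)


class TestVIP:
    def test_symmetric_predictors_all_one(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=300)
        X = np.tile(t[:, None], (1, 8)) + 1e-9 * rng.normal(size=(300, 8))
        y = t.copy()
        model = fit_plsr(X, y, n_components=1)
        assert np.allclose(vip(model), 1.0, atol=1e-3)

    def test_mean_square_identity(self):
        rng = np.random.default_rng(7)
        for a in (1, 2, 5):
            X = rng.normal(size=(120, 34))
            y = X @ rng.normal(size=34) + rng.normal(size=120)
            model = fit_plsr(X, y, n_components=a)
            assert np.mean(vip(model) ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_predictor_closed_form(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3000, 34))
        y = X[:, 5].copy()
        model = fit_plsr(X, y, n_components=1)
        v = vip(model)
        assert v[5] == pytest.approx(np.sqrt(34.0), rel=0.02)
        assert np.all(np.delete(v, 5) < 0.35)

    def test_zero_explained_variance_raises(self):
        rng = np.random.default_rng(9)
        model = fit_plsr(rng.normal(size=(30, 3)), rng.normal(size=30),
                         n_components=1)
        object.__setattr__(model, "ssy", np.zeros(1))
        with pytest.raises(ValueError):
            vip(model)


class TestSelectNComponents:
    def test_two_direction_recovery(self):
        hits = 0
        for seed in range(10):
            X, y = two_direction_data(seed=seed)
            n_star, curve, _ = select_ncomponents(X, y, max_components=6,
                                                  seed=seed)
            hits += (n_star == 2)
        assert hits >= 9

    def test_pure_noise_selects_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 10))
        y = rng.normal(size=200)
        n_star, curve, _ = select_ncomponents(X, y, max_components=6, seed=0)
        assert n_star == 1

    def test_leave_one_out_accepted(self):
        X, y = two_direction_data(n=40)
        n_star, curve, _ = select_ncomponents(X, y, max_components=3,
                                              folds=40, seed=0)
        assert 1 <= n_star <= 3

    def test_too_many_folds_raise(self):
        X, y = two_direction_data(n=30)
        with pytest.raises(ValueError):
            select_ncomponents(X, y, max_components=2, folds=31)

    def test_deterministic_in_seed(self):
        X, y = two_direction_data()
        a = select_ncomponents(X, y, max_components=5, seed=123)
        b = select_ncomponents(X, y, max_components=5, seed=123)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])


class TestResidualsOnSex:
    def test_identical_residual_pattern_null(self):
        res = residuals_on_sex([1.0, 2.0, 1.0, 2.0], [1, 1, -1, -1])
        assert res.r2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert not res.sex_related

    def test_sex_effect_detected(self):
        rng = np.random.default_rng(11)
        sex = np.tile([1, -1], 2000)
        resid = 0.1 * sex + rng.normal(0, 1.0, 4000)
        res = residuals_on_sex(resid, sex)
        assert res.p < 0.001
        assert res.sex_related

    def test_single_sex_raises(self):
        with pytest.raises(ValueError):
            residuals_on_sex([1.0, 2.0], [1, 1])

    def test_alpha_default(self):
        import inspect

        sig = inspect.signature(residuals_on_sex)
        assert sig.parameters["alpha"].default == 0.001


class TestWaistGirthSweep:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 150
        waist_raw = rng.uniform(70.0, 120.0, n)
        other = 0.5 * waist_raw + rng.normal(0, 5.0, n)
        height = 180.0
        norm = pd.DataFrame({"waist_girth": waist_raw / height,
                             "other": other / height})
        Z = (norm - norm.mean()) / norm.std(ddof=1)
        y = 2.0 * Z["waist_girth"].to_numpy() + rng.normal(0, 0.3, n)
        model = fit_plsr(Z, y, n_components=1, y_name="PC1")
        return Z, waist_raw, norm, {"PC1": model}

    def test_trajectory_affine_in_waist(self):
        Z, waist_raw, norm, models = self._setup()
        out = waist_girth_sweep(models, Z, waist_raw, 180.0,
                                norm["waist_girth"].mean(),
                                norm["waist_girth"].std(ddof=1))
        x = out["waist_girth_cm"].to_numpy()
        y = out["PC1"].to_numpy()
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        assert np.max(np.abs(resid)) < 1e-9
        assert y[-1] > y[0]  # waist-linked PC rises with waist girth

    def test_out_of_support_raises(self):
        Z, waist_raw, norm, models = self._setup()
        with pytest.raises(ValueError, match="support"):
            waist_girth_sweep(models, Z, waist_raw, 180.0,
                              norm["waist_girth"].mean(),
                              norm["waist_girth"].std(ddof=1),
                              waist_values_cm=[waist_raw.max() + 10.0])


class TestVarianceDecomposition:
    def test_arithmetic_contract(self):
        out = variance_decomposition({"PC1": 0.8}, {"PC1": 0.5})
        row = out[out.pc == "PC1"].iloc[0]
        assert row.explained_pct == pytest.approx(40.0)
        assert row.unexplained_pct == pytest.approx(10.0)

    def test_zero_r2_explains_nothing(self):
        out = variance_decomposition({"PC1": 0.0, "PC2": 0.0},
                                     {"PC1": 0.6, "PC2": 0.2})
        total = out[out.pc == "total"].iloc[0]
        assert total.explained_pct == pytest.approx(0.0)
        assert total.share_total_pct == pytest.approx(80.0)

    def test_mismatched_pc_sets_raise(self):
        with pytest.raises(ValueError):
            variance_decomposition({"PC1": 0.5}, {"PC2": 0.5})
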