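"""PLS1 diagnostics: closed form, VIP, cross-validation, permutations."""

import numpy as np
import pandas as pd
import pytest

from hepamark import chemometrics as chem
from hepamark.preprocess import pareto_scale


def _random_scaled(n, p, seed, informative=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    beta = rng.normal(size=p) if informative else np.zeros(p)
    y = X @ beta + rng.normal(scale=0.5, size=n)
    return X, y


class TestFitPLS1:
    def test_perfect_single_predictor(self):
        n = 12
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        X = np.zeros((n, 4))
        X[:, 2] = x - x.mean()
        y = 3.0 * x + 1.0
        m = chem.fit_pls1(X, y)
        assert m.r2y == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(m.weights), [0, 0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_weight_is_normalized_covariance_direction(self, seed):
        X, y = _random_scaled(8, 5, seed)
        m = chem.fit_pls1(X, y)
        # independent brute-force closed form
        yc = y - y.mean()
        cov = np.array([sum(X[i, j] * yc[i] for i in range(8)) for j in range(5)])
        expected = cov / np.sqrt((cov**2).sum())
        np.testing.assert_allclose(m.weights, expected, atol=1e-12)

    def test_r2y_matches_brute_force_rss(self):
        X, y = _random_scaled(30, 10, 4)
        m = chem.fit_pls1(X, y)
        resid = y - m.predict(X)
        r2y = 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert m.r2y == pytest.approx(r2y, abs=1e-10)

    def test_orthogonal_response_refused(self):
        # columns constructed orthogonal to the centered response
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.array([[1.0, 2.0]] * 4)  # constant columns, X'yc = 0
        with pytest.raises(chem.DegenerateModelError):
            chem.fit_pls1(X, y)

    def test_prediction_in_trait_units(self):
        X, y = _random_scaled(40, 6, 5)
        y = y + 500.0  # trait offset, e.g. liver weight in grams
        m = chem.fit_pls1(X, y)
        assert m.predict(X).mean() == pytest.approx(y.mean(), rel=0.05)


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        n, p = 20, 9
        rng = np.random.default_rng(6)
        t = rng.normal(size=n)
        X = np.outer(t, np.ones(p))
        y = t.copy()
        m = chem.fit_pls1(X, y)
        np.testing.assert_allclose(chem.vip(m), 1.0, atol=1e-12)

    def test_single_active_variable_among_100(self):
        n, p = 25, 100
        rng = np.random.default_rng(7)
        X = np.zeros((n, p))
        X[:, 41] = rng.normal(size=n)
        X[:, 41] -= X[:, 41].mean()
        y = X[:, 41] * 2.0
        v = chem.vip(chem.fit_pls1(X, y))
        assert v[41] == pytest.approx(10.0, abs=1e-9)
        assert np.all(np.delete(v, 41) == 0)

    @pytest.mark.parametrize("seed", [8, 9])
    def test_mean_squared_vip_is_one(self, seed):
        X, y = _random_scaled(15, 30, seed)
        v = chem.vip(chem.fit_pls1(X, y))
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-12)


class TestRMSEE:
    def test_perfect_fit_is_zero(self):
        n = 10
        t = np.linspace(-1, 1, n)
        X = t[:, None]
        y = 2.0 * t
        m = chem.fit_pls1(X, y)
        assert chem.rmsee(m, X, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_dof_formula(self):
        # residuals all +/- r with n=11 and one component: r*sqrt(11/9)
        n, r = 11, 0.37
        resid = r * np.array([1, -1] * 5 + [1], dtype=float)
        y = np.arange(n, dtype=float)
        model = chem.PLSModel(
            weights=np.array([1.0]), scores=np.zeros(n), x_loadings=np.array([1.0]),
            y_loading=1.0, y_center=0.0, r2x=1.0, r2y=1.0, vip=np.array([1.0]),
        )
        X = (y - resid)[:, None]  # predict(X) = y - resid
        assert chem.rmsee(model, X, y) == pytest.approx(r * np.sqrt(11 / 9), abs=1e-12)

    def test_small_n_refused(self):
        X, y = _random_scaled(8, 3, 1)
        m = chem.fit_pls1(X, y)
        with pytest.raises(ValueError):
            chem.rmsee(m, X[:2], y[:2])

    def test_rmsee_usually_below_rmsecv(self):
        # fit optimism: estimation error <= cross-validated error on most
        # informative datasets
        wins = 0
        for seed in range(50):
            X, y = _random_scaled(30, 8, seed + 100)
            Xdf = pd.DataFrame(X)
            m = chem.fit_pls1(pareto_scale(Xdf).scaled, y)
            e_fit = chem.rmsee(m, pareto_scale(Xdf).scaled, y)
            _, e_cv = chem.q2_rmsecv(Xdf, y, folds=7, seed=seed)
            wins += e_fit <= e_cv
        assert wins >= 45


class TestCrossValidation:
    def test_noiseless_latent_relation_predicts_almost_perfectly(self):
        # y exactly linear in one latent direction of X (the asymptotic
        # regime a one-component model can represent)
        rng = np.random.default_rng(10)
        t = rng.normal(size=50)
        loadings = np.array([1.0, -2.0, 0.5, 0.7, 3.0])
        X = np.outer(t, loadings) + rng.normal(scale=1e-3, size=(50, 5))
        y = 2.0 * t
        q2, rmsecv = chem.q2_rmsecv(X, y, folds=7, seed=0)
        assert q2 > 0.99
        assert rmsecv < 0.2 * y.std()

    def test_permuted_response_has_no_predictive_ability(self):
        X, y = _random_scaled(40, 12, 11)
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            q2, _ = chem.q2_rmsecv(X, rng.permutation(y), folds=7, seed=seed)
            q2s.append(q2)
        assert np.mean(q2s) < 0.1

    def test_leave_one_out_runs(self):
        X, y = _random_scaled(12, 4, 12)
        q2, rmsecv = chem.q2_rmsecv(X, y, folds=12, seed=0)
        assert np.isfinite(q2) and np.isfinite(rmsecv)

    def test_q2_never_exceeds_r2y(self):
        for seed in range(10):
            X, y = _random_scaled(30, 15, seed + 300)
            Xdf = pd.DataFrame(X)
            m = chem.fit_pls1(pareto_scale(Xdf).scaled, y)
            q2, _ = chem.q2_rmsecv(Xdf, y, folds=7, seed=seed)
            assert q2 <= m.r2y + 1e-12

    def test_bad_fold_counts_refused(self):
        X, y = _random_scaled(10, 3, 1)
        with pytest.raises(ValueError):
            chem.q2_rmsecv(X, y, folds=1)
        with pytest.raises(ValueError):
            chem.q2_rmsecv(X, y, folds=11)


class TestPermutationValidation:
    def test_deterministic_given_seed(self):
        X, y = _random_scaled(25, 10, 14)
        a = chem.permutation_validation(X, y, n_perm=20, seed=3)
        b = chem.permutation_validation(X, y, n_perm=20, seed=3)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.intercept_q2 == b.intercept_q2

    def test_informative_data_validates(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 30))
        y = X[:, :5] @ np.ones(5) + rng.normal(scale=0.3, size=40)
        res = chem.permutation_validation(X, y, n_perm=100, seed=4)
        assert res.intercept_q2 < 0
        assert res.original_q2 > res.records["q2"].max()

    def test_constant_response_flagged_degenerate(self):
        X, _ = _random_scaled(10, 4, 16)
        res = chem.permutation_validation(X, np.ones(10), n_perm=10, seed=0)
        assert res.degenerate

    def test_record_count_and_correlation_range(self):
        X, y = _random_scaled(20, 6, 17)
        res = chem.permutation_validation(X, y, n_perm=30, seed=5)
        assert len(res.records) == 30
        assert res.records["corr"].between(-1, 1).all()


class TestPCAOutlierScreen:
    def test_null_calibration(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(300, 10))
        res = chem.pca_outlier_screen(X, n_pc=2, alpha=0.05)
        assert 0.01 <= res.flags.mean() <= 0.12

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(40, 6))
        u, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        X[0] += 10 * X.std() * vt[0]
        res = chem.pca_outlier_screen(X, n_pc=2)
        assert res.flags[0]

    def test_invalid_n_pc(self):
        with pytest.raises(ValueError):
            chem.pca_outlier_screen(np.zeros((10, 3)), n_pc=0)

    def test_rank_deficiency_reduces_components(self):
        rng = np.random.default_rng(20)
        col = rng.normal(size=20)
        X = np.outer(col, [1.0, 2.0, 3.0])  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            res = chem.pca_outlier_screen(X, n_pc=2)
        assert res.n_pc == 1
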