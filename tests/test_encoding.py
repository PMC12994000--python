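"""Lasso GLM: closed-form oracles, KKT conditions, CV bookkeeping."""

import warnings

import numpy as np
import pytest

from dqnencode.design import DesignMatrix
from dqnencode.encoding import (
    EncodingConfig,
    cross_validate_many,
    cross_validate_voxel,
    lasso_fit,
    pearson_r,
    select_lambda,
)
from tests.conftest import make_session_designs


class TestLassoFit:
    def test_null_threshold_gives_zero_vector(self, rng):
        """lambda >= max_j |x_j . y| / N shrinks every coefficient to 0."""
        x = rng.standard_normal((100, 8))
        y = rng.standard_normal(100)
        lam_max = np.abs(x.T @ y).max() / 100
        beta = lasso_fit(x, y, lam_max * 1.001)
        np.testing.assert_array_equal(beta, 0)

    def test_orthonormal_design_soft_threshold(self, rng):
        """On an orthonormal design the lasso is coordinate-wise
        soft-thresholding of the OLS solution."""
        q, _ = np.linalg.qr(rng.standard_normal((200, 50)))
        x = q * np.sqrt(200)  # columns with x_j.x_j = N
        beta_true = rng.standard_normal(50) * (rng.random(50) < 0.4)
        y = x @ beta_true + 0.1 * rng.standard_normal(200)
        lam = 0.07
        beta = lasso_fit(x, y, lam)
        z = x.T @ y / 200
        expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0)
        np.testing.assert_allclose(beta, expected, atol=1e-6)

    def test_lambda_zero_matches_ols(self, rng):
        x = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        beta = lasso_fit(x, y, 0.0)
        ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_kkt_conditions_at_convergence(self, rng):
        x = rng.standard_normal((150, 20))
        y = x @ (rng.standard_normal(20) * (rng.random(20) < 0.3)) + rng.standard_normal(150)
        lam = 0.05
        beta = lasso_fit(x, y, lam)
        grad = x.T @ (y - x @ beta) / 150
        tol = 1e-4
        assert np.all(np.abs(grad[beta == 0]) <= lam + tol)
        active = beta != 0
        np.testing.assert_allclose(np.abs(grad[active]), lam, atol=tol)

    def test_l1_norm_monotone_in_lambda(self, rng):
        x = rng.standard_normal((100, 15))
        y = rng.standard_normal(100)
        norms = [np.abs(lasso_fit(x, y, lam)).sum() for lam in (0.01, 0.05, 0.1, 0.3)]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[np.nan]]), np.array([1.0]), 0.1)


class TestPearson:
    def test_identity_and_sign_flip(self, rng):
        y = rng.standard_normal(50)
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert pearson_r(-y, y) == pytest.approx(-1.0)

    def test_zero_variance_prediction_scores_zero_with_warning(self, rng):
        with pytest.warns(RuntimeWarning):
            assert pearson_r(np.zeros(10), rng.standard_normal(10)) == 0.0

    def test_scale_invariance_under_positive_affine(self, rng):
        pred, y = rng.standard_normal((2, 60))
        r0 = pearson_r(pred, y)
        assert pearson_r(3.0 * pred + 5.0, y) == pytest.approx(r0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.zeros(4), np.zeros(5))


class TestSelectLambda:
    def test_flat_curve_returns_grid_midpoint(self):
        grid = np.array([0.01, 0.05, 0.2])
        assert select_lambda(grid, np.ones(3)) == pytest.approx((0.01 + 0.2) / 2)

    def test_published_plateau_midpoint_is_0p07(self):
        """A plateau spanning [0.04, 0.1] fixes lambda at its midpoint 0.07."""
        grid = np.array([0.005, 0.01, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.5])
        curve = np.array([0.10, 0.12, 0.15, 0.20, 0.200, 0.199, 0.1995, 0.15, 0.05])
        assert select_lambda(grid, curve) == pytest.approx(0.07)

    def test_single_strict_maximum(self):
        grid = np.array([0.01, 0.05, 0.2])
        assert select_lambda(grid, np.array([0.1, 0.5, 0.1])) == pytest.approx(0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(np.array([]), np.array([]))


class TestCrossValidation:
    def test_each_session_tested_exactly_once(self, iid_designs, rng):
        """Fold bookkeeping: fold s holds out session s exactly, with the
        model trained on the remaining four sessions — verified by manually
        re-deriving every fold."""
        w = np.zeros(10)
        w[[1, 4, 7]] = [1.0, -1.0, 0.5]
        resp = [d.values.T @ w + 0.1 * rng.standard_normal(200) for d in iid_designs]
        cfg = EncodingConfig()
        res = cross_validate_voxel(iid_designs, resp, cfg)
        assert res.r_per_session.shape == (5,)
        for test in range(5):
            train = [s for s in range(5) if s != test]
            assert len(train) == 4 and test not in train
            manual = np.mean(
                [lasso_fit(iid_designs[s].values.T, resp[s], cfg.fixed_lambda)
                 for s in train], axis=0,
            )
            pred = iid_designs[test].values.T @ manual
            assert res.r_per_session[test] == pytest.approx(
                pearson_r(pred, resp[test]), abs=1e-12
            )

    def test_coefficient_averaging_contract(self, iid_designs, rng):
        """Per-fold coefficients equal the mean of the 4 per-training-session
        lasso fits, and the prediction uses that average."""
        w = np.zeros(10)
        w[[0, 3]] = [1.2, -0.8]
        resp = [d.values.T @ w + 0.2 * rng.standard_normal(200) for d in iid_designs]
        cfg = EncodingConfig()
        res = cross_validate_voxel(iid_designs, resp, cfg)
        test = 2
        manual = np.mean(
            [lasso_fit(iid_designs[s].values.T, resp[s], cfg.fixed_lambda)
             for s in range(5) if s != test],
            axis=0,
        )
        np.testing.assert_allclose(res.coefficients[test], manual, atol=1e-12)
        pred = iid_designs[test].values.T @ manual
        assert res.r_per_session[test] == pytest.approx(pearson_r(pred, resp[test]))

    def test_noise_free_recovery(self, iid_designs):
        """Noise-free 3-predictor mixtures are recovered with mean r >= 0.99."""
        rng = np.random.default_rng(42)
        w = np.zeros(10)
        w[[2, 5, 8]] = rng.normal(0, 1, 3)
        resp = [d.values.T @ w for d in iid_designs]
        res = cross_validate_voxel(iid_designs, resp, EncodingConfig(fixed_lambda=0.07))
        assert res.mean_r >= 0.99

    def test_true_support_active_at_minimal_lambda(self, iid_designs):
        rng = np.random.default_rng(7)
        w = np.zeros(10)
        support = [1, 4, 9]
        w[support] = rng.normal(0, 1, 3) + np.sign(rng.normal(size=3)) * 0.5
        resp = [d.values.T @ w for d in iid_designs]
        cfg = EncodingConfig(fixed_lambda=0.005)
        res = cross_validate_voxel(iid_designs, resp, cfg)
        active = set(np.flatnonzero(np.abs(res.mean_coefficients) > 1e-8))
        assert set(support) <= active

    def test_pure_noise_mean_r_small(self, iid_designs):
        """Null bound: |mean r| stays within ~2/sqrt(N) per session."""
        means = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            resp = [r.standard_normal(200) for _ in range(5)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cross_validate_voxel(iid_designs, resp, EncodingConfig())
            means.append(res.mean_r)
        assert np.max(np.abs(means)) < 0.15

    def test_predictor_mismatch_rejected(self, iid_designs, rng):
        bad = list(iid_designs)
        bad[1] = DesignMatrix(bad[1].values[:8], ["conv1"] * 8, True)
        with pytest.raises(ValueError, match="predictor"):
            cross_validate_voxel(bad, [rng.standard_normal(200) for _ in range(5)])

    def test_batched_equals_per_voxel(self, iid_designs, rng):
        ys = [rng.standard_normal((200, 3)) for _ in range(5)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_mat, mean_r, _ = cross_validate_many(iid_designs, ys)
            for v in range(3):
                res = cross_validate_voxel(iid_designs, [y[:, v] for y in ys])
                np.testing.assert_allclose(res.r_per_session, r_mat[v], atol=1e-10)

    def test_concatenate_mode_differs_but_recovers(self, iid_designs):
        rng = np.random.default_rng(3)
        w = np.zeros(10)
        w[[0, 5]] = [1.0, 1.0]
        resp = [d.values.T @ w + 0.1 * rng.standard_normal(200) for d in iid_designs]
        res = cross_validate_voxel(iid_designs, resp, EncodingConfig(fit_mode="concatenate"))
        assert res.mean_r > 0.95


class TestEncodeAllVoxels:
    def test_table_preserves_voxels_and_coordinates(self, iid_designs, rng):
        from dqnencode.design import VoxelSeries
        from dqnencode.encoding import encode_all_voxels

        coords = np.array([[1, 2, 3], [4, 5, 6]])
        w = np.zeros(10)
        w[[0, 5]] = [1.0, -1.0]
        voxels = [
            VoxelSeries(
                np.vstack([d.values.T @ w + 0.2 * rng.standard_normal(200)] * 2),
                coords,
            )
            for d in iid_designs
        ]
        table = encode_all_voxels(iid_designs, voxels, EncodingConfig())
        assert len(table) == 2
        np.testing.assert_array_equal(table[["x", "y", "z"]].to_numpy(), coords)
        # identical voxel series -> identical results (determinism)
        assert table["mean_r"].iloc[0] == table["mean_r"].iloc[1]
        assert table["mean_r"].iloc[0] > 0.9


class TestLambdaCurve:
    def test_plateau_selection_on_computed_curve(self, iid_designs):
        """The mean-r curve over the grid feeds the plateau-midpoint rule."""
        from dqnencode.encoding import lambda_curve

        rng = np.random.default_rng(8)
        w = np.zeros(10)
        w[[2, 7]] = [1.0, 0.8]
        resp = [
            (d.values.T @ w + 1.0 * rng.standard_normal(200)).reshape(-1, 1)
            for d in iid_designs
        ]
        cfg = EncodingConfig(lambda_grid=np.array([0.005, 0.02, 0.07, 0.2, 0.5]))
        curve = lambda_curve(iid_designs, resp, cfg)
        assert curve.shape == (5,)
        lam = select_lambda(cfg.lambda_grid, curve, cfg.plateau_band_fraction)
        assert cfg.lambda_grid[0] <= lam <= cfg.lambda_grid[-1]
        # heavy shrinkage must hurt: the curve falls off by lambda = 0.5
        assert curve[-1] < curve.max()


class TestNoiseCeiling:
    def test_realized_r_tracks_theoretical_ceiling(self):
        """With equal signal and noise variance the correlation ceiling is
        sqrt(0.5); realized CV r should sit near it (small repetition set;
        the full 50-rep check runs in the acceptance suite)."""
        rs = []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            designs = make_session_designs(iid=True, seed=200 + rep)
            w = np.zeros(10)
            w[rng.choice(10, 3, replace=False)] = rng.normal(0, 1, 3)
            sig = [d.values.T @ w for d in designs]
            sd = np.concatenate(sig).std()
            resp = [s + rng.normal(0, sd, 200) for s in sig]
            res = cross_validate_voxel(designs, resp, EncodingConfig())
            rs.append(res.mean_r)
        assert np.mean(rs) == pytest.approx(np.sqrt(0.5), abs=0.05)
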