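import numpy as np
import pandas as pd
import pytest

import ftirlip as fl
from ftirlip.chemometrics import CVResult, day_segmented_cv, select_components
from ftirlip.errors import ResponseError, SegmentationError
from ftirlip.simulate import generate_fold_fixture


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = rng.random(6)
        X = np.outer(rng.normal(size=30), direction)
        scores, loadings, evr = fl.pca_scores(X, scaling="center")
        assert evr[0] == pytest.approx(1.0)

    def test_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 5))
        scores, loadings, evr = fl.pca_scores(X, scaling="center")
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose((scores**2).sum(axis=0), eigvals, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((25, 4))
        _, loadings, _ = fl.pca_scores(X)
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_planted_clusters_separate_in_pc1(self):
        rng = np.random.default_rng(3)
        direction = np.ones(10) / np.sqrt(10)
        a = 0.05 * rng.standard_normal((30, 10)) + 2.0 * direction
        b = 0.05 * rng.standard_normal((30, 10)) - 2.0 * direction
        scores, _, _ = fl.pca_scores(np.vstack([a, b]))
        pc1 = scores[:, 0]
        gap = abs(pc1[:30].mean() - pc1[30:].mean())
        within = max(pc1[:30].std(), pc1[30:].std())
        assert gap > 5 * within

    def test_autoscale_mode_and_min_samples(self):
        rng = np.random.default_rng(4)
        X = rng.random((10, 3)) * [1, 100, 1e4]
        scores, _, evr = fl.pca_scores(X, scaling="autoscale")
        assert np.isfinite(scores).all() and evr.sum() <= 1 + 1e-12
        with pytest.raises(ValueError):
            fl.pca_scores(X[:1])


class TestPLS:
    def test_exact_univariate_recovery(self):
        x = np.linspace(0, 1, 12)[:, None]
        y = 2 * x[:, 0] + 1
        m = fl.pls_fit(x, y, 1)
        np.testing.assert_allclose(fl.pls_predict(m, x), y, atol=1e-10)

    def test_full_rank_equals_ols(self):
        X, y, _ = generate_fold_fixture(20, 5, noise_sd=0.3, seed=5)
        m = fl.pls_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = Xc @ beta + y.mean()
        np.testing.assert_allclose(fl.pls_predict(m, X), ols_pred, atol=1e-6)

    def test_matches_sklearn_cross_check(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y, _ = generate_fold_fixture(30, 8, noise_sd=0.5, seed=6)
        for k in (1, 3, 5):
            ours = fl.pls_fit(X, y, k)
            ref = sklearn_pls.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                fl.pls_predict(ours, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_orthogonal_response_gives_mean_prediction(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.random(6)] * 2 + [rng.random(6)] * 2)  # rank 2
        X = np.vstack([X, X])  # y orthogonal to column space after centering
        y = np.array([1.0, -1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0])
        Xc = X - X.mean(axis=0)
        assert np.allclose(Xc.T @ (y - y.mean()), 0, atol=1e-12)
        m = fl.pls_fit(X, y, 2)
        np.testing.assert_allclose(m.coefficients(), 0, atol=1e-10)
        np.testing.assert_allclose(fl.pls_predict(m, X), y.mean(), atol=1e-10)

    def test_prediction_is_affine(self):
        X, y, _ = generate_fold_fixture(15, 4, noise_sd=0.1, seed=8)
        m = fl.pls_fit(X, y, 3)
        x1, x2, alpha = X[0], X[1], 0.3
        lhs = fl.pls_predict(m, (alpha * x1 + (1 - alpha) * x2)[None, :])[0]
        rhs = alpha * fl.pls_predict(m, x1[None, :])[0] + (1 - alpha) * fl.pls_predict(
            m, x2[None, :]
        )[0]
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_mean_row_predicts_mean_response(self):
        X, y, _ = generate_fold_fixture(15, 4, noise_sd=0.1, seed=9)
        m = fl.pls_fit(X, y, 2)
        np.testing.assert_allclose(
            fl.pls_predict(m, X.mean(axis=0)[None, :])[0], y.mean(), atol=1e-10
        )

    def test_zero_variance_response_rejected(self):
        X, _, _ = generate_fold_fixture(10, 3, seed=10)
        with pytest.raises(ResponseError):
            fl.pls_fit(X, np.ones(10), 2)

    def test_component_bounds_enforced(self):
        X, y, _ = generate_fold_fixture(10, 3, seed=11)
        with pytest.raises(ValueError):
            fl.pls_fit(X, y, 10)


class TestDaySegmentedCV:
    def test_each_sample_predicted_exactly_once(self):
        X, y, _ = generate_fold_fixture(48, 6, noise_sd=0.2, seed=12)
        days = np.repeat(np.arange(1, 13), 4)
        cv = day_segmented_cv(X, y, days, max_ncomp=5)
        assert np.isfinite(cv.pred_matrix).all()
        assert len(cv.predictions) == 48
        assert set(cv.predictions["segment"]) == set(range(1, 13))

    def test_recovers_noise_floor_on_planted_model(self):
        sigma = 0.5
        X, y, _ = generate_fold_fixture(200, 20, noise_sd=sigma, seed=13)
        days = np.arange(200) % 10 + 1
        cv = day_segmented_cv(X, y, days, max_ncomp=25)
        assert abs(cv.rmse_by_ncomp.min() - sigma) <= 0.25 * sigma

    def test_no_spurious_skill_on_noise_only_response(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((120, 15))
        y = rng.standard_normal(120)
        days = np.arange(120) % 8 + 1
        cv = day_segmented_cv(X, y, days, max_ncomp=10)
        assert (cv.rmse_by_ncomp >= 0.8 * y.std(ddof=1)).all()

    def test_single_day_rejected(self):
        X, y, _ = generate_fold_fixture(10, 3, seed=15)
        with pytest.raises(SegmentationError):
            day_segmented_cv(X, y, np.ones(10), max_ncomp=2)

    def test_leak_freedom(self):
        """Held-out-day predictions must not depend on that day's y values:
        filling the day's responses with garbage leaves its own fold's
        predictions bitwise stable (the day is absent from fitting and
        centering)."""
        X, y, _ = generate_fold_fixture(60, 8, noise_sd=0.3, seed=16)
        days = np.arange(60) % 6 + 1
        base = day_segmented_cv(X, y, days, max_ncomp=4)
        test_mask = days == 3
        y_bad = y.copy()
        y_bad[test_mask] = 1e6
        cv2 = day_segmented_cv(X, y_bad, days, max_ncomp=4)
        np.testing.assert_allclose(
            cv2.pred_matrix[test_mask], base.pred_matrix[test_mask], atol=1e-10
        )

    def test_per_fold_emsc_reference_uses_training_days_only(self):
        """Reconstruct one fold by hand: EMSC reference = mean of training
        derivative spectra, model fit on EMSC-corrected training rows only.
        The CV predictions must match this leak-free reconstruction."""
        from ftirlip.chemometrics import _emsc_rows
        from ftirlip.preprocess import PreprocessConfig

        rng = np.random.default_rng(17)
        wn = 3100.0 - 6.0 * np.arange(30)
        truth = rng.random(30)
        X = np.vstack(
            [rng.uniform(0.8, 1.2) * truth + rng.normal(0, 0.01, 30) for _ in range(40)]
        )
        y = X @ rng.random(30)
        days = np.arange(40) % 4 + 1
        cv = day_segmented_cv(X, y, days, max_ncomp=3, emsc_refit=True, wavenumbers=wn)
        mask = days == 2
        cfg = PreprocessConfig()
        ref = X[~mask].mean(axis=0)  # training days only
        Xtr = _emsc_rows(wn, X[~mask], ref, cfg)
        Xte = _emsc_rows(wn, X[mask], ref, cfg)
        for k in (1, 2, 3):
            m = fl.pls_fit(Xtr, y[~mask], k)
            np.testing.assert_allclose(
                cv.pred_matrix[mask, k - 1], fl.pls_predict(m, Xte), atol=1e-10
            )


class TestSelectComponents:
    @pytest.mark.parametrize(
        "rmse,se,expected",
        [
            ([5.0, 3.0, 2.00, 1.99, 1.98], [0.1, 0.1, 0.1, 0.1, 0.05], 3),
            ([5.0, 4.0, 3.0, 2.0, 1.0], [0.0] * 5, 5),  # steep: rule returns argmin
            ([2.0, 2.0, 2.0], [0.1] * 3, 1),  # constant: parsimony
            ([3.0, 1.0, 1.05], [0.0, 0.0, 0.0], 2),
        ],
    )
    def test_one_standard_error_rule(self, rmse, se, expected):
        assert select_components(rmse, se) == expected

    def test_never_exceeds_argmin(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            rmse = rng.random(12)
            se = rng.random(12) * 0.2
            assert select_components(rmse, se) <= int(np.argmin(rmse)) + 1


class TestCalibrationMetrics:
    @staticmethod
    def make_cv(y, yhat, ncomp=3):
        preds = np.tile(yhat[:, None], (1, ncomp))
        return CVResult(
            response="demo",
            rmse_by_ncomp=np.full(ncomp, float(np.sqrt(np.mean((yhat - y) ** 2)))),
            se_by_ncomp=np.zeros(ncomp),
            chosen_ncomp=ncomp,
            predictions=pd.DataFrame({"segment": np.arange(y.size), "y_true": y, "y_pred": yhat}),
            pred_matrix=preds,
        )

    def test_rpd_identity_exact_before_rounding(self):
        rng = np.random.default_rng(19)
        y = rng.normal(20, 6, 50)
        yhat = y + rng.normal(0, 1.5, 50)
        row = fl.calibration_metrics(self.make_cv(y, yhat))
        assert row.rpd_cv * row.rmsecv == pytest.approx(row.sd, abs=1e-12)
        assert row.range_min <= row.mean <= row.range_max

    def test_perfect_predictions(self):
        y = np.linspace(0, 10, 20)
        row = fl.calibration_metrics(self.make_cv(y, y.copy()))
        assert np.isinf(row.rpd_cv) and row.r2_cv == 1.0 and row.rmsecv == 0.0

    def test_constant_reference_rejected(self):
        y = np.full(10, 3.0)
        with pytest.raises(ResponseError):
            fl.calibration_metrics(self.make_cv(y, y + 0.1))


class TestBuildCalibration:
    def test_exclusions_reduce_sample_count(self, design210):
        rep = fl.build_calibration(
            design210.spectra,
            design210.fatty_acids,
            ["unsaturation_index"],
            exclusions=fl.EARLY_GROWTH_EXCLUSIONS,
            max_ncomp=5,
        )
        assert len(rep.cv_results["unsaturation_index"].predictions) == 201

    def test_empty_exclusions_keep_all(self, design210):
        rep = fl.build_calibration(
            design210.spectra, design210.fatty_acids, ["total_lipid"], max_ncomp=5
        )
        assert len(rep.cv_results["total_lipid"].predictions) == 210

    def test_missing_response_named(self, design210):
        with pytest.raises(ResponseError, match="C99:9"):
            fl.build_calibration(
                design210.spectra, design210.fatty_acids, ["C99:9"], max_ncomp=3
            )

    def test_report_shape_and_formatting(self, design210):
        rep = fl.build_calibration(
            design210.spectra,
            design210.fatty_acids,
            ["unsaturation_index", "total_lipid"],
            max_ncomp=5,
        )
        df = rep.to_frame()
        assert list(df["response"]) == ["unsaturation_index", "total_lipid"]
        text = rep.formatted()
        assert "RPD_CV" in text and "unsaturation_index" in text
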