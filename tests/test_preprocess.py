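import numpy as np
import pytest

import ftirlip as fl
from ftirlip.errors import DegenerateSampleError, GridError
from ftirlip.preprocess import PreprocessConfig, _emsc_design
from ftirlip.spectra import SampleMeta, SpectrumSet


def make_set(grid, rows):
    rows = np.atleast_2d(rows)
    meta = [
        SampleMeta(f"s_20C_d01_b{i + 1}", "s", 20.0, 1, i + 1) for i in range(rows.shape[0])
    ]
    return SpectrumSet(grid, rows, meta)


GRID = 4000.0 - 6.0 * np.arange(584)


class TestSavitzkyGolay:
    def test_exact_on_quadratic(self):
        s = make_set(GRID, GRID**2)
        out = fl.savitzky_golay_derivative(s)
        # 2nd derivative of nu^2 is exactly 2 everywhere (polynomial degree
        # <= fit order); half-window trimmed from each end
        assert out.n_wavenumbers == 584 - 8
        np.testing.assert_allclose(out.absorbance, 2.0, atol=1e-8)

    def test_zero_on_affine(self):
        s = make_set(GRID, 3.0 * GRID + 7.0)
        out = fl.savitzky_golay_derivative(s)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-8)

    def test_gaussian_matches_analytic_second_derivative(self):
        c, sigma = 2000.0, 15.0
        y = np.exp(-0.5 * ((GRID - c) / sigma) ** 2)
        out = fl.savitzky_golay_derivative(make_set(GRID, y))
        w = out.wavenumbers
        analytic = (
            ((w - c) ** 2 / sigma**4 - 1.0 / sigma**2)
            * np.exp(-0.5 * ((w - c) / sigma) ** 2)
        )
        # the 9-point window's smoothing bias dominates: 2.0e-3 for this
        # sigma/grid combination by the closed-form oracle
        assert np.max(np.abs(out.absorbance[0] - analytic)) < 2.5e-3

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(584), rng.random(584)
        a, b = 2.5, -1.25
        d = lambda v: fl.savitzky_golay_derivative(make_set(GRID, v)).absorbance[0]
        np.testing.assert_allclose(d(a * x + b * y), a * d(x) + b * d(y), atol=1e-10)

    def test_spacing_scaling_switch(self):
        y = np.sin(GRID / 100.0)
        scaled = fl.savitzky_golay_derivative(make_set(GRID, y))
        raw = fl.savitzky_golay_derivative(
            make_set(GRID, y), PreprocessConfig(sg_scale_spacing=False)
        )
        np.testing.assert_allclose(scaled.absorbance * 36.0, raw.absorbance, rtol=1e-10)

    def test_non_uniform_grid_rejected(self):
        grid = np.array([4000.0, 3990.0, 3986.0, 3980.0, 3975.0, 3969.0, 3962.0, 3956.0, 3950.0])
        with pytest.raises(GridError):
            fl.savitzky_golay_derivative(make_set(grid, np.ones(9)))

    def test_window_larger_than_grid_rejected(self):
        grid = 4000.0 - 6.0 * np.arange(5)
        with pytest.raises(GridError):
            fl.savitzky_golay_derivative(make_set(grid, np.ones(5)))


class TestEMSC:
    grid = 3100.0 - 6.0 * np.arange(51)

    def test_identity_when_sample_equals_reference(self):
        rng = np.random.default_rng(1)
        ref = rng.random(self.grid.size)
        s = make_set(self.grid, ref)
        out, coeffs = fl.emsc_correct(s, reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)
        c = coeffs[0]
        np.testing.assert_allclose([c.a, c.b, c.c, c.d], [0, 1, 0, 0], atol=1e-10)

    def test_offset_and_scale_recovered(self):
        rng = np.random.default_rng(2)
        ref = rng.random(self.grid.size)
        s = make_set(self.grid, 0.5 + 2.0 * ref)
        out, coeffs = fl.emsc_correct(s, reference=ref)
        c = coeffs[0]
        np.testing.assert_allclose([c.a, c.b, c.c, c.d], [0.5, 2.0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_random_coefficients_recovered_vs_normal_equations(self):
        # plant (a, b, c, d), recover via the package, and cross-check the
        # solve against an explicit normal-equations oracle
        rng = np.random.default_rng(3)
        ref = rng.random(self.grid.size)
        t = 2 * (self.grid - self.grid.min()) / (self.grid.max() - self.grid.min()) - 1
        rows, truth = [], []
        for _ in range(5):
            a0, b0, c0, d0 = rng.uniform(-1, 1, 4)
            b0 += 2.0  # keep b away from 0
            rows.append(a0 + c0 * t + d0 * t**2 + b0 * ref)
            truth.append((a0, b0, c0, d0))
        s = make_set(self.grid, np.vstack(rows))
        _, coeffs = fl.emsc_correct(s, reference=ref)
        for c, (a0, b0, c0, d0) in zip(coeffs, truth):
            np.testing.assert_allclose([c.a, c.b, c.c, c.d], [a0, b0, c0, d0], atol=1e-8)
        # oracle: explicit normal equations for the first sample
        D = _emsc_design(self.grid, ref, 2)
        beta = np.linalg.solve(D.T @ D, D.T @ rows[0])
        np.testing.assert_allclose(
            beta, [truth[0][0], truth[0][2], truth[0][3], truth[0][1]], atol=1e-8
        )

    def test_order_zero_reduces_to_classic_msc(self):
        rng = np.random.default_rng(4)
        ref = rng.random(self.grid.size)
        z = 0.3 + 1.7 * ref + rng.normal(0, 0.01, ref.size)
        s = make_set(self.grid, z)
        out, coeffs = fl.emsc_correct(s, PreprocessConfig(emsc_poly_order=0), reference=ref)
        # 2-parameter least-squares oracle: z ~ a + b*ref
        D = np.column_stack([np.ones_like(ref), ref])
        a_hat, b_hat = np.linalg.solve(D.T @ D, D.T @ z)
        np.testing.assert_allclose([coeffs[0].a, coeffs[0].b], [a_hat, b_hat], atol=1e-10)
        np.testing.assert_allclose(out.absorbance[0], (z - a_hat) / b_hat, atol=1e-10)

    def test_exact_for_samples_in_span(self):
        rng = np.random.default_rng(5)
        ref = rng.random(self.grid.size)
        t = 2 * (self.grid - self.grid.min()) / (self.grid.max() - self.grid.min()) - 1
        z = -0.2 + 0.9 * t - 0.4 * t**2 + 1.3 * ref
        out, _ = fl.emsc_correct(make_set(self.grid, z), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_degenerate_b_raises_naming_sample(self):
        ref = np.sin(self.grid / 50)
        s = make_set(self.grid, np.ones(self.grid.size))  # constant: b ~ 0
        with pytest.raises(DegenerateSampleError, match="s_20C_d01_b1"):
            fl.emsc_correct(s, reference=ref)


class TestPipeline:
    def test_counts_and_grid(self, design210):
        corrected, coeffs = fl.preprocess_pipeline(design210.spectra)
        assert corrected.n_samples == 210 and len(coeffs) == 210
        # combined region of the half-window-trimmed grid
        w = corrected.wavenumbers
        in_ch = (w >= 2800) & (w <= 3100)
        in_fp = (w >= 500) & (w <= 1800)
        assert np.all(in_ch | in_fp)
        assert w.max() <= 3976.0 and w.min() >= 526.0  # trimmed ends gone

    def test_emsc_idempotent_with_same_reference(self, experiment):
        # correcting already-corrected spectra against the *same* reference
        # fits (a, b, c, d) = (0, 1, 0, 0): residuals are orthogonal to the
        # design, so the output is unchanged
        averaged = fl.average_technical_replicates(experiment.spectra)
        deriv = fl.savitzky_golay_derivative(averaged)
        restricted = fl.select_region(deriv, PreprocessConfig().emsc_regions)
        ref = restricted.absorbance.mean(axis=0)
        once, _ = fl.emsc_correct(restricted, reference=ref)
        twice, coeffs = fl.emsc_correct(once, reference=ref)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-10)
        np.testing.assert_allclose([c.b for c in coeffs], 1.0, atol=1e-8)

    def test_planted_scatter_removed(self):
        # common truth spectrum under per-sample scatter: EMSC collapses the
        # between-sample spread by many orders of magnitude
        grid = 3100.0 - 6.0 * np.arange(51)
        rng = np.random.default_rng(6)
        truth = rng.random(51)
        t = 2 * (grid - grid.min()) / (grid.max() - grid.min()) - 1
        rows = np.vstack(
            [
                rng.uniform(0.7, 1.3) * truth
                + rng.uniform(-0.1, 0.1)
                + rng.uniform(-0.05, 0.05) * t
                + rng.uniform(-0.05, 0.05) * t**2
                for _ in range(20)
            ]
        )
        s = make_set(grid, rows)
        pre_rms = np.sqrt(((rows - rows.mean(axis=0)) ** 2).mean())
        out, _ = fl.emsc_correct(s)
        post = out.absorbance
        post_rms = np.sqrt(((post - post.mean(axis=0)) ** 2).mean())
        assert post_rms < 1e-6 * pre_rms

    def test_no_hidden_randomness(self, experiment):
        a, _ = fl.preprocess_pipeline(experiment.spectra)
        b, _ = fl.preprocess_pipeline(experiment.spectra)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)


class TestConfig:
    def test_invalid_sg_settings_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=8)
        with pytest.raises(ValueError):
            PreprocessConfig(sg_deriv=3, sg_polyorder=2)

    def test_dict_round_trip(self):
        cfg = PreprocessConfig(sg_window=11, emsc_poly_order=1)
        back = PreprocessConfig.from_dict(cfg.to_dict())
        assert back == cfg
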