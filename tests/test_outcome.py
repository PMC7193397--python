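"""Penalized quasi-Poisson outcome model: fitting, smoothing, prediction."""

import numpy as np
import pytest

from gpsdrf.outcome import GPSOutcomeModel
from gpsdrf.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="module")
def small_fit_inputs(rng=None):
    g = np.random.default_rng(11)
    n = 600
    z = np.exp(g.normal(3.5, 0.5, n))
    r = np.exp(-0.5 * g.normal(size=n) ** 2)  # GPS-like in (0, 1]
    eta = 1.0 + 0.4 * (z - z.min()) / np.ptp(z)
    y = g.poisson(np.exp(eta))
    return y, z, r


class TestFitting:
    def test_constant_counts_fit_constant(self):
        g = np.random.default_rng(0)
        z = np.exp(g.normal(3.5, 0.4, 300))
        r = g.uniform(0.1, 0.9, 300)
        y = np.full(300, 7.0)
        res = GPSOutcomeModel(y, z, r, n_knots=10).fit()
        assert np.allclose(res.fittedvalues, 7.0, rtol=1e-6)
        assert res.deviance == pytest.approx(0.0, abs=1e-8)

    def test_edf_bounds(self, fitted_natural):
        out = fitted_natural.outcome
        assert 3.0 <= out.edf <= 3.0 + out.basis.n_knots

    def test_linear_signal_recovered(self, small_fit_inputs):
        y, z, r = small_fit_inputs
        res = GPSOutcomeModel(y, z, r, n_knots=20).fit()
        zt = (z - z.min()) / np.ptp(z)
        eta_true = 1.0 + 0.4 * zt
        corr = np.corrcoef(np.log(res.fittedvalues), eta_true)[0, 1]
        assert corr > 0.5
        # average fitted level within a few percent of the average truth
        assert res.fittedvalues.mean() == pytest.approx(
            np.exp(eta_true + 0.0).mean(), rel=0.1
        )

    def test_validation_errors(self):
        g = np.random.default_rng(1)
        z = np.exp(g.normal(size=100))
        r = g.uniform(0.1, 1, 100)
        with pytest.raises(ValueError, match="integer"):
            GPSOutcomeModel(np.full(100, 1.5), z, r, n_knots=10)
        with pytest.raises(ValueError, match="positive"):
            GPSOutcomeModel(np.ones(100), z, np.zeros(100), n_knots=10)

    def test_deviance_nonincreasing_in_flexibility(self, default_series, gps_results):
        """Smaller smoothing parameter never increases the deviance."""
        y = default_series.deaths("natural")
        m = GPSOutcomeModel(y, default_series.z, gps_results.actual_gps(), n_knots=30)
        devs = [m.fit(smooth=lam).deviance for lam in (0.01, 1.0, 100.0, 1e4)]
        assert all(a <= b + 1e-6 for a, b in zip(devs, devs[1:]))

    def test_heavy_smoothing_shrinks_radial_coefficients(self, default_series, gps_results):
        y = default_series.deaths("natural")
        m = GPSOutcomeModel(y, default_series.z, gps_results.actual_gps(), n_knots=30)
        light = m.fit(smooth=1e-3)
        heavy = m.fit(smooth=1e10)
        assert np.linalg.norm(heavy.beta[3:]) < 1e-3 * max(
            np.linalg.norm(light.beta[3:]), 1e-12
        )

    def test_gcv_grid_selection_matches_brute_force(self, default_series, gps_results):
        """The selected grid point minimizes the GCV score over the grid."""
        y = default_series.deaths("cvd")
        grid = np.logspace(-2, 4, 10)
        m = GPSOutcomeModel(y, default_series.z, gps_results.actual_gps(), n_knots=25)
        res = m.fit(lambda_grid=grid, refine=False)
        scores = [m._pirls(lam)["gcv_sel"] for lam in grid]
        assert res.lambda_smooth == pytest.approx(grid[int(np.argmin(scores))])


class TestPrediction:
    def test_in_sample_consistency(self, fitted_natural, default_series):
        """Predicting day i's potential outcome at its own observed
        exposure reproduces the training fitted mean."""
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        z = default_series.z
        for i in (5, 200, 1000):
            yhat = out.predict_potential(gps, float(z[i]))
            assert yhat[i] == pytest.approx(out.fittedvalues[i], rel=1e-10)

    def test_no_effect_surface_gives_flat_curves(self, fitted_natural, default_series):
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        beta0 = out.beta.copy()
        try:
            out.beta = np.zeros_like(out.beta)
            out.beta[0] = np.log(25.0)
            a = out.predict_potential(gps, 20.0)
            b = out.predict_potential(gps, 80.0)
            assert np.allclose(a, 25.0)
            assert np.allclose(a, b)
        finally:
            out.beta = beta0

    def test_affine_rescaling_invariance(self):
        """Min-max standardization makes predictions invariant to affine
        rescaling of the raw exposure/GPS inputs."""
        g = np.random.default_rng(3)
        n = 400
        z = np.exp(g.normal(3.5, 0.5, n))
        r = g.uniform(0.05, 0.95, n)
        y = g.poisson(20.0, n)
        res1 = GPSOutcomeModel(y, z, r, n_knots=15).fit(smooth=1.0)
        res2 = GPSOutcomeModel(y, 3.0 * z + 7.0, 0.5 * r + 0.1, n_knots=15).fit(smooth=1.0)
        rows1, _ = res1.basis.evaluate(z[:20], r[:20])
        rows2, _ = res2.basis.evaluate(3.0 * z[:20] + 7.0, 0.5 * r[:20] + 0.1)
        assert np.allclose(rows1 @ res1.beta, rows2 @ res2.beta, atol=1e-8)

    def test_nonpositive_z_rejected(self, fitted_natural):
        with pytest.raises(ValueError):
            fitted_natural.outcome.predict_potential(fitted_natural.exposure, 0.0)


class TestAgainstGLMOracle:
    def test_smoothing_limit_equals_unpenalized_glm(self, default_series, gps_results):
        """At enormous smoothing the fit collapses onto the unpenalized
        Poisson GLM on [1, z~, r~] (independent statsmodels oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        y = default_series.deaths("natural")
        z = default_series.z
        R = gps_results.actual_gps()
        m = GPSOutcomeModel(y, z, R, n_knots=30)
        res = m.fit(smooth=1e12)
        zt = (z - z.min()) / np.ptp(z)
        rt = (R - R.min()) / np.ptp(R)
        X = np.column_stack([np.ones(len(y)), zt, rt])
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(res.beta[:3], glm.params, atol=1e-6)
        assert np.linalg.norm(res.beta[3:]) < 1e-5

    def test_quasi_poisson_points_match_poisson_ml(self, default_series, gps_results):
        """Dispersion rescales uncertainty only: fitting the same data
        twice yields identical coefficients regardless of the dispersion
        estimate's value."""
        y = default_series.deaths("resp")
        m = GPSOutcomeModel(y, default_series.z, gps_results.actual_gps(), n_knots=20)
        a = m.fit(smooth=5.0)
        b = m.fit(smooth=5.0)
        assert np.array_equal(a.beta, b.beta)
        assert a.dispersion != 1.0  # a free scale, estimated from Pearson
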