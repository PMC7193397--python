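"""Causal estimands: aDRF, AD, DAD and the bootstrap."""

import numpy as np
import pytest

from gpsdrf.estimands import (
    bootstrap_ci,
    estimate_ad,
    estimate_adrf,
    estimate_conditional_adrf,
    estimate_dad,
    exact_dad,
)


class TestADRF:
    def test_conditional_with_all_true_predicate_is_unconditional(self, fitted_natural):
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        grid = np.linspace(20, 100, 7)
        a = estimate_adrf(out, gps, z_grid=grid)
        b = estimate_adrf(out, gps, z_grid=grid,
                          subset_mask=np.ones(out.nobs, dtype=bool))
        assert np.array_equal(a.point, b.point)

    def test_temperature_strata_partition_days(self, fitted_natural, default_series):
        t03 = default_series.temp_lag03
        masks = [(t03 <= 10), (t03 > 10) & (t03 <= 23), (t03 > 23)]
        assert sum(m.sum() for m in masks) == default_series.n
        grid = np.array([30.0, 60.0])
        curves = [
            estimate_conditional_adrf(
                fitted_natural.outcome, fitted_natural.exposure, t03, s, z_grid=grid
            )
            for s in ("low", "medium", "high")
        ]
        # stratum averages recombine to the overall average
        weights = np.array([m.sum() for m in masks]) / default_series.n
        overall = estimate_adrf(fitted_natural.outcome, fitted_natural.exposure,
                                z_grid=grid).point
        recombined = sum(w * c.point for w, c in zip(weights, curves))
        assert np.allclose(recombined, overall, rtol=1e-10)

    def test_empty_grid_rejected(self, fitted_natural):
        with pytest.raises(ValueError):
            estimate_adrf(fitted_natural.outcome, fitted_natural.exposure,
                          z_grid=np.array([]))

    def test_unknown_stratum_rejected(self, fitted_natural, default_series):
        with pytest.raises(ValueError, match="stratum"):
            estimate_conditional_adrf(
                fitted_natural.outcome, fitted_natural.exposure,
                default_series.temp_lag03, "tropical",
            )


class TestAD:
    def test_zero_above_max_exposure_with_warning(self, fitted_natural, default_series):
        z_star = float(default_series.z.max()) + 1.0
        with pytest.warns(UserWarning, match="AD is 0"):
            res = estimate_ad(fitted_natural.outcome, fitted_natural.exposure, z_star)
        assert res.point == 0.0
        assert res.n_treated == 0

    def test_additive_over_disjoint_treated_sets(self, fitted_natural, default_series):
        """AD over all treated days equals the sum of contributions of any
        partition of those days (computed directly from the definition)."""
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        z = default_series.z
        y = out.model.y
        res = estimate_ad(out, gps, 40.0)
        ycf = out.predict_potential(gps, 40.0)
        treated = z > 40.0
        half = np.zeros_like(treated)
        half[np.where(treated)[0][::2]] = True
        part1 = np.sum(y[half] - ycf[half])
        part2 = np.sum(y[treated & ~half] - ycf[treated & ~half])
        assert res.point == pytest.approx(part1 + part2, rel=1e-12)

    def test_n_treated_recorded(self, fitted_natural, default_series):
        res = estimate_ad(fitted_natural.outcome, fitted_natural.exposure, 40.0)
        assert res.n_treated == int((default_series.z > 40.0).sum())


class TestDAD:
    def test_monte_carlo_matches_exact_enumeration(self, fitted_natural):
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        exact = exact_dad(out, gps, 40.0)
        mc = estimate_dad(out, gps, 40.0, mc_draws=10_000, seed=99)
        assert abs(mc.point - exact) / abs(exact) < 0.01

    def test_degenerate_pstar_equals_ad_at_that_value(self, fitted_natural):
        """With a single below-threshold exposure value, DAD collapses to
        the fixed-value AD at that value, exactly."""
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        z = out.model.z
        v = float(z[z <= 40.0].min())
        z_backup = out.model.z.copy()
        try:
            out.model.z = np.where(z <= 40.0, v, z)  # collapse p* support
            dad = estimate_dad(out, gps, 40.0, mc_draws=50, seed=1).point
            y = out.model.y
            treated = out.model.z > 40.0
            ycf = out.predict_potential(gps, v)
            ad_at_v = float(np.sum(y[treated] - ycf[treated]))
            assert dad == pytest.approx(ad_at_v, rel=1e-12)
        finally:
            out.model.z = z_backup

    def test_mc_error_shrinks_like_inverse_sqrt(self, fitted_natural):
        """|MC - exact| across M in {100,400,1600,6400} scales ~ 1/sqrt(M)."""
        out, gps = fitted_natural.outcome, fitted_natural.exposure
        exact = exact_dad(out, gps, 40.0)
        Ms = [100, 400, 1600, 6400]
        errs = []
        for M in Ms:
            vals = [
                abs(estimate_dad(out, gps, 40.0, mc_draws=M, seed=s).point - exact)
                for s in range(8)
            ]
            errs.append(np.mean(vals))
        slope = np.polyfit(1 / np.sqrt(Ms), errs, 1)[0]
        assert slope > 0

    def test_requires_days_on_both_sides(self, fitted_natural, default_series):
        with pytest.raises(ValueError, match="both sides"):
            estimate_dad(fitted_natural.outcome, fitted_natural.exposure,
                         float(default_series.z.max()) + 1, mc_draws=10)

    def test_mc_se_reported(self, fitted_natural):
        res = estimate_dad(fitted_natural.outcome, fitted_natural.exposure,
                           40.0, mc_draws=500, seed=3)
        assert res.mc_se is not None and res.mc_se > 0


class TestBootstrap:
    def test_constant_estimator_zero_width_ci(self, fitted_natural):
        m = fitted_natural.model
        lo, hi, reps, nf = bootstrap_ci(
            m.y, m.series.z, m.exposure_model.exog,
            lambda *a: 3.14, n_boot=50, seed=0, n_knots=10,
            freeze_lambda=1.0,
        )
        assert lo == hi == pytest.approx(3.14)
        assert nf == 0

    def test_same_seed_reproducible(self, fitted_natural):
        m = fitted_natural.model

        def est(out_b, gps_b, idx, s):
            return estimate_ad(out_b, gps_b, 40.0).point

        kw = dict(n_boot=50, n_knots=10, freeze_lambda=1.0)
        a = bootstrap_ci(m.y, m.series.z, m.exposure_model.exog, est, seed=7, **kw)
        b = bootstrap_ci(m.y, m.series.z, m.exposure_model.exog, est, seed=7, **kw)
        assert a[0] == b[0] and a[1] == b[1]
        assert np.array_equal(a[2], b[2])

    def test_ci_brackets_point_estimate(self, fitted_natural):
        m = fitted_natural.model
        point = fitted_natural.attributable_deaths(40.0).point

        def est(out_b, gps_b, idx, s):
            return estimate_ad(out_b, gps_b, 40.0).point

        lo, hi, reps, nf = bootstrap_ci(
            m.y, m.series.z, m.exposure_model.exog, est,
            n_boot=60, seed=11, n_knots=30,
            freeze_lambda=fitted_natural.outcome.lambda_smooth,
        )
        assert lo < hi
        assert lo < point < hi

    def test_too_few_replicates_rejected(self, fitted_natural):
        m = fitted_natural.model
        with pytest.raises(ValueError):
            bootstrap_ci(m.y, m.series.z, m.exposure_model.exog,
                         lambda *a: 0.0, n_boot=10, seed=0)
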