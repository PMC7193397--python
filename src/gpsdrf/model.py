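"""High-level model/results interface tying the pipeline together.

:class:`GPSDoseResponse` is the entry point for a per-cause analysis: it
owns the study series, builds and fits the exposure (GPS) model and the
penalized quasi-Poisson outcome model, and its :meth:`~GPSDoseResponse.fit`
returns a :class:`GPSDoseResponseResults` from which the causal estimands,
balance diagnostics and bootstrap confidence intervals are obtained::

    series, truth = generate(GeneratorConfig(seed=7))
    res = GPSDoseResponse(series, cause="natural").fit()
    curve = res.adrf()
    impact = res.attributable_deaths(40.0, ci=True, n_boot=200, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimands as _est
from .balance import balance_report
from .data import StudyTimeSeries
from .estimands import EstimandResult
from .exposure import ExposureModel, ExposureResults
from .outcome import GPSOutcomeModel, GPSOutcomeResults

__all__ = ["GPSDoseResponse", "GPSDoseResponseResults"]


class GPSDoseResponse:
    """GPS-based dose-response model for one cause of death.

    Parameters
    ----------
    series : StudyTimeSeries
        Validated daily analysis table.
    cause : str
        Which death-count column to model ("natural", "cvd" or "resp").
    n_knots : int
        Radial knots of the bivariate outcome smoother.
    lambda_grid : array_like, optional
        Candidate smoothing parameters for GCV selection.
    """

    def __init__(self, series: StudyTimeSeries, cause: str = "natural",
                 n_knots: int = 50, lambda_grid=None):
        self.series = series
        self.cause = cause
        self.n_knots = n_knots
        self.lambda_grid = lambda_grid
        self.y = series.deaths(cause)
        self.exposure_model = ExposureModel.from_series(series)

    def fit(self, smooth: float | None = None) -> "GPSDoseResponseResults":
        gps_res = self.exposure_model.fit()
        r = gps_res.actual_gps()
        outcome_model = GPSOutcomeModel(self.y, self.series.z, r, self.n_knots)
        out_res = outcome_model.fit(smooth=smooth, lambda_grid=self.lambda_grid)
        return GPSDoseResponseResults(model=self, exposure=gps_res, outcome=out_res)


@dataclass
class GPSDoseResponseResults:
    """Fitted exposure + outcome pair with estimand and diagnostic methods."""

    model: GPSDoseResponse = field(repr=False)
    exposure: ExposureResults
    outcome: GPSOutcomeResults

    # ------------------------------------------------------------------
    # estimands
    # ------------------------------------------------------------------
    def adrf(self, z_grid=None, ci: bool = False, n_boot: int = 1000,
             seed=None, **boot_kw) -> EstimandResult:
        """Average dose-response function on an exposure grid."""
        res = _est.estimate_adrf(self.outcome, self.exposure, z_grid=z_grid)
        if ci:
            grid = res.grid

            def est(out_b, gps_b, idx, rep_seed):
                return _est.estimate_adrf(out_b, gps_b, z_grid=grid).point

            res.ci_low, res.ci_high, res.replicates, res.n_boot_failed = (
                self._bootstrap(est, n_boot, seed, **boot_kw)
            )
            res.n_boot = n_boot
        return res

    def conditional_adrf(self, stratum: str, z_grid=None) -> EstimandResult:
        """aDRF within a temperature stratum ('low', 'medium', 'high')."""
        return _est.estimate_conditional_adrf(
            self.outcome, self.exposure, self.model.series.temp_lag03,
            stratum, z_grid=z_grid,
        )

    def attributable_deaths(self, z_star: float, ci: bool = False,
                            n_boot: int = 1000, seed=None, **boot_kw) -> EstimandResult:
        """AD(z*): deaths attributable to exposures above the threshold."""
        res = _est.estimate_ad(self.outcome, self.exposure, z_star)
        if ci:
            def est(out_b, gps_b, idx, rep_seed):
                return _est.estimate_ad(out_b, gps_b, z_star).point

            res.ci_low, res.ci_high, res.replicates, res.n_boot_failed = (
                self._bootstrap(est, n_boot, seed, **boot_kw)
            )
            res.n_boot = n_boot
        return res

    def dad(self, z_star: float, mc_draws: int = 1000, seed=None,
            ci: bool = False, n_boot: int = 1000, **boot_kw) -> EstimandResult:
        """DAD(z*): attributable deaths under the distributional scenario."""
        res = _est.estimate_dad(self.outcome, self.exposure, z_star,
                                mc_draws=mc_draws, seed=seed)
        if ci:
            def est(out_b, gps_b, idx, rep_seed):
                return _est.estimate_dad(
                    out_b, gps_b, z_star, mc_draws=mc_draws, seed=rep_seed
                ).point

            res.ci_low, res.ci_high, res.replicates, res.n_boot_failed = (
                self._bootstrap(est, n_boot, seed, **boot_kw)
            )
            res.n_boot = n_boot
        return res

    def _bootstrap(self, estimator, n_boot, seed, **boot_kw):
        m = self.model
        boot_kw.setdefault("n_knots", m.n_knots)
        boot_kw.setdefault("lambda_grid", m.lambda_grid)
        return _est.bootstrap_ci(
            m.y, m.series.z, m.exposure_model.exog, estimator,
            n_boot=n_boot, seed=seed, **boot_kw,
        )

    # ------------------------------------------------------------------
    # diagnostics
    # ------------------------------------------------------------------
    def balance(self, covariates=None) -> pd.DataFrame:
        """Marginal vs GPS-adjusted covariate-balance table."""
        return balance_report(self.exposure, self.model.series, covariates)

    def summary(self) -> str:
        s = self.model.series
        curve = _est.estimate_adrf(
            self.outcome, self.exposure,
            z_grid=np.percentile(s.z, [5, 50, 95]),
        ).point
        lines = [
            f"GPS dose-response analysis - cause: {self.model.cause}",
            "=" * 56,
            f"{'days analysed':<30}{s.n}",
            f"{'exposure mean / sd':<30}"
            f"{s.z.mean():.1f} / {s.z.std(ddof=1):.1f}",
            f"{'sigma_Z (exposure model)':<30}{self.exposure.sigma_z:.4f}",
            f"{'outcome lambda (GCV)':<30}{self.outcome.lambda_smooth:.4g}",
            f"{'outcome edf':<30}{self.outcome.edf:.2f}",
            f"{'dispersion':<30}{self.outcome.dispersion:.3f}",
            f"{'aDRF at z p5/p50/p95':<30}"
            + " / ".join(f"{v:.2f}" for v in curve),
        ]
        return "\n".join(lines)

    def plot_adrf(self, result: EstimandResult | None = None, ax=None):
        """Plot an aDRF curve (requires matplotlib)."""
        import matplotlib.pyplot as plt  # local import: plotting is optional

        if result is None:
            result = self.adrf()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(result.grid, result.point, color="C0")
        if result.ci_low is not None:
            ax.fill_between(result.grid, result.ci_low, result.ci_high,
                            alpha=0.25, color="C0")
        ax.set_xlabel("exposure (lag 0-1), μg/m³")
        ax.set_ylabel(f"expected daily deaths ({self.model.cause})")
        return ax
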