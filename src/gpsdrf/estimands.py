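"""Causal estimands: dose-response curves and attributable deaths.

Given the fitted exposure (GPS) and outcome models, the package estimates

* the average dose-response function (aDRF)
      mu(z) = (1/N) sum_i Y_i(z),
  the average daily death count had every day's exposure been set to z;
* conditional aDRFs mu(z; x), averages over the days whose covariates
  satisfy a predicate (built-in: temperature-at-lag-0-3 strata
  "up to 10 C", "10-23 C", "over 23 C");
* attributable deaths under a fixed-cap counterfactual
      AD(z*) = sum_{i: Z_i > z*} (Y_i - Y_i(z*));
* distributional attributable deaths
      DAD(z*) = int ( sum_{i: Z_i > z*} (Y_i - Y_i(z)) ) p*(z) dz,
  with p* the empirical exposure distribution of the days at or below the
  threshold, evaluated by Monte-Carlo draws (and exactly, by enumerating
  the finite support, in :func:`exact_dad`).

Uncertainty comes from an i.i.d. nonparametric bootstrap over day-rows of
the fully-constructed analysis table: each replicate refits the exposure
model, recomputes the GPS, refits the outcome model and recomputes the
estimand; confidence intervals are the 5th/95th percentiles (90%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exposure import ExposureModel, ExposureResults
from .outcome import GPSOutcomeModel, GPSOutcomeResults

__all__ = [
    "EstimandResult",
    "TEMPERATURE_STRATA",
    "temperature_stratum_mask",
    "estimate_adrf",
    "estimate_conditional_adrf",
    "estimate_ad",
    "estimate_dad",
    "exact_dad",
    "bootstrap_ci",
    "InstabilityError",
]

logger = logging.getLogger(__name__)

#: Temperature (lag 0-3) strata used for the conditional aDRF, deg C.
TEMPERATURE_STRATA = {
    "low": lambda t: t <= 10.0,
    "medium": lambda t: (t > 10.0) & (t <= 23.0),
    "high": lambda t: t > 23.0,
}


class InstabilityError(RuntimeError):
    """Too many bootstrap replicates failed to fit."""


@dataclass
class EstimandResult:
    """Point estimate of a causal estimand with optional bootstrap 90% CI."""

    kind: str  # adrf | adrf_conditional | AD | DAD
    point: np.ndarray | float
    grid: np.ndarray | None = None
    ci_low: np.ndarray | float | None = None
    ci_high: np.ndarray | float | None = None
    z_star: float | None = None
    n_treated: int | None = None
    mc_draws: int | None = None
    mc_se: float | None = None
    n_boot: int | None = None
    n_boot_failed: int | None = None
    stratum: str | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)


def default_z_grid(z, size: int = 100) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return np.linspace(z.min(), z.max(), size)


def _potential_matrix(outcome_res, gps_res, z_values):
    """(len(z_values), N) matrix of predicted potential outcomes."""
    return np.vstack(
        [outcome_res.predict_potential(gps_res, z) for z in z_values]
    )


def temperature_stratum_mask(temp_lag03, stratum: str) -> np.ndarray:
    try:
        rule = TEMPERATURE_STRATA[stratum]
    except KeyError:
        raise ValueError(
            f"unknown stratum {stratum!r}; expected one of {tuple(TEMPERATURE_STRATA)}"
        ) from None
    return rule(np.asarray(temp_lag03, dtype=float))


# ----------------------------------------------------------------------
# dose-response curves
# ----------------------------------------------------------------------
def estimate_adrf(
    outcome_res: GPSOutcomeResults,
    gps_res: ExposureResults,
    z_grid=None,
    subset_mask=None,
) -> EstimandResult:
    """Average dose-response function on a grid of exposure values.

    ``z_grid`` defaults to 100 equally spaced points over the observed
    exposure range.  ``subset_mask`` restricts the average to a subset of
    days (conditional aDRF); the default averages over all days.
    """
    if z_grid is None:
        z_grid = default_z_grid(outcome_res.model.z)
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size == 0:
        raise ValueError("z_grid must be non-empty")
    kind = "adrf"
    if subset_mask is not None:
        subset_mask = np.asarray(subset_mask, dtype=bool)
        if not subset_mask.any():
            raise ValueError("subset rule selects no days")
        kind = "adrf_conditional"
    curve = np.empty(z_grid.size)
    for j, z in enumerate(z_grid):
        yhat = outcome_res.predict_potential(gps_res, z)
        curve[j] = yhat.mean() if subset_mask is None else yhat[subset_mask].mean()
    return EstimandResult(kind=kind, point=curve, grid=z_grid)


def estimate_conditional_adrf(
    outcome_res: GPSOutcomeResults,
    gps_res: ExposureResults,
    temp_lag03,
    stratum: str,
    z_grid=None,
) -> EstimandResult:
    """aDRF within a named temperature stratum (low / medium / high)."""
    mask = temperature_stratum_mask(temp_lag03, stratum)
    if not mask.any():
        raise ValueError(f"temperature stratum {stratum!r} contains no days")
    res = estimate_adrf(outcome_res, gps_res, z_grid=z_grid, subset_mask=mask)
    res.stratum = stratum
    return res


# ----------------------------------------------------------------------
# attributable deaths
# ----------------------------------------------------------------------
def estimate_ad(
    outcome_res: GPSOutcomeResults,
    gps_res: ExposureResults,
    z_star: float,
) -> EstimandResult:
    """Attributable deaths under the fixed-cap counterfactual z*.

    Sums, over the "treated" days (Z_i > z*), the observed count minus the
    predicted potential outcome at z*.  With no treated days the estimate
    is 0 (with a warning), not an error.
    """
    if z_star <= 0:
        raise ValueError("z_star must be positive")
    y = outcome_res.model.y
    z = outcome_res.model.z
    treated = z > z_star
    n_treated = int(treated.sum())
    if n_treated == 0:
        warnings.warn(
            f"no day exceeds z*={z_star:g}; AD is 0 by construction",
            stacklevel=2,
        )
        return EstimandResult(kind="AD", point=0.0, z_star=z_star, n_treated=0)
    y_cf = outcome_res.predict_potential(gps_res, z_star)
    ad = float(np.sum(y[treated] - y_cf[treated]))
    return EstimandResult(kind="AD", point=ad, z_star=z_star, n_treated=n_treated)


def _ad_at_values(outcome_res, gps_res, z_values, treated):
    """AD^m for each counterfactual exposure value (treated set fixed)."""
    y_tr_sum = float(outcome_res.model.y[treated].sum())
    out = np.empty(len(z_values))
    for j, zv in enumerate(z_values):
        y_cf = outcome_res.predict_potential(gps_res, zv)
        out[j] = y_tr_sum - float(y_cf[treated].sum())
    return out


def estimate_dad(
    outcome_res: GPSOutcomeResults,
    gps_res: ExposureResults,
    z_star: float,
    mc_draws: int = 1000,
    seed=None,
) -> EstimandResult:
    """Distributional attributable deaths by Monte-Carlo integration.

    Counterfactual exposures are drawn uniformly from the observed
    exposures of the days at or below z* (the empirical p*); for each draw
    the fixed-value AD is computed and the draws are averaged.  The
    Monte-Carlo standard error of the mean is reported.
    """
    if z_star <= 0:
        raise ValueError("z_star must be positive")
    z = outcome_res.model.z
    treated = z > z_star
    below = z[~treated]
    if not treated.any() or below.size == 0:
        raise ValueError(
            f"DAD undefined at z*={z_star:g}: need days on both sides of the threshold"
        )
    rng = np.random.default_rng(seed)
    draws = rng.choice(below, size=int(mc_draws), replace=True)
    # identical draws share one curve evaluation
    values, counts = np.unique(draws, return_counts=True)
    ad_vals = _ad_at_values(outcome_res, gps_res, values, treated)
    ad_m = np.repeat(ad_vals, counts)
    dad = float(ad_m.mean())
    mc_se = float(ad_m.std(ddof=1) / np.sqrt(len(ad_m))) if len(ad_m) > 1 else 0.0
    return EstimandResult(
        kind="DAD",
        point=dad,
        z_star=z_star,
        n_treated=int(treated.sum()),
        mc_draws=int(mc_draws),
        mc_se=mc_se,
    )


def exact_dad(
    outcome_res: GPSOutcomeResults,
    gps_res: ExposureResults,
    z_star: float,
) -> float:
    """DAD by exact enumeration of the finite support of p*.

    Averages the fixed-value AD over every below-threshold observed
    exposure (weighted by multiplicity); the Monte-Carlo estimator
    converges to this value as the number of draws grows.
    """
    z = outcome_res.model.z
    treated = z > z_star
    below = z[~treated]
    if not treated.any() or below.size == 0:
        raise ValueError(
            f"DAD undefined at z*={z_star:g}: need days on both sides of the threshold"
        )
    values, counts = np.unique(below, return_counts=True)
    ad_vals = _ad_at_values(outcome_res, gps_res, values, treated)
    return float(np.average(ad_vals, weights=counts))


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def bootstrap_ci(
    y,
    z,
    exog,
    estimator,
    n_boot: int = 1000,
    seed=None,
    n_knots: int = 50,
    lambda_grid=None,
    freeze_lambda: float | None = None,
    extra=None,
    max_fail_frac: float = 0.05,
):
    """Nonparametric day-level bootstrap of an estimand.

    Parameters
    ----------
    y, z, exog : arrays
        Counts, exposures and the exposure-model covariate matrix of the
        fully-constructed analysis table (lagged variables already
        attached; rows are resampled together).
    estimator : callable
        ``estimator(outcome_res, gps_res, idx, rep_seed)`` returning a
        scalar or vector; ``idx`` are the resampled row indices (for
        estimators needing auxiliary per-day data via ``extra``).
    n_boot : int
        Number of replicates (>= 50).
    freeze_lambda : float, optional
        Fix the outcome smoothing parameter inside replicates instead of
        re-selecting it by GCV (faster; slightly narrower intervals).
    extra : dict, optional
        Auxiliary per-day arrays, resampled alongside and passed through.

    Returns
    -------
    (ci_low, ci_high, replicates, n_failed)
        Percentile 5%/95% bounds; replicates failing to fit are dropped
        and counted, and more than ``max_fail_frac`` failures raise
        :class:`InstabilityError`.
    """
    if n_boot < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    exog = np.asarray(exog, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_boot)
    reps = []
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            gps_b = ExposureModel(z[idx], exog[idx]).fit()
            r_b = gps_b.actual_gps()
            model_b = GPSOutcomeModel(y[idx], z[idx], r_b, n_knots=n_knots)
            if freeze_lambda is not None:
                out_b = model_b.fit(smooth=freeze_lambda)
            else:
                out_b = model_b.fit(lambda_grid=lambda_grid)
            reps.append(np.asarray(estimator(out_b, gps_b, idx, int(rep_seeds[b]))))
        except Exception as exc:  # noqa: BLE001 - any fit failure counts
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_fail_frac * n_boot:
        raise InstabilityError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to fit"
        )
    replicates = np.vstack(reps)
    ci_low = np.percentile(replicates, 5.0, axis=0)
    ci_high = np.percentile(replicates, 95.0, axis=0)
    if replicates.shape[1] == 1:
        ci_low, ci_high = float(ci_low[0]), float(ci_high[0])
        replicates = replicates.ravel()
    return ci_low, ci_high, replicates, n_failed
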