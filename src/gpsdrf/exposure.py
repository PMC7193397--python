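"""Parametric log-normal exposure model and the generalized propensity score.

The exposure model assumes

    log(Z_i) ~ N(alpha_0 + alpha_X' X_i, sigma_Z),

with Z_i the lag 0-1 pollutant exposure and X_i a rich covariate vector:
day-of-week dummies (Monday reference), holiday and influenza indicators,
a piecewise-linear calendar spline (5 df per year, equally spaced knots), a
cubic spline of temperature at lag 0-3 (5 df, quantile knots), linear and
quadratic humidity, and a July-August indicator capturing the summer
population dip.

The generalized propensity score (GPS) is then the conditional density of
the exposure given the covariates,

    r(z; x) = (2 pi sigma_Z^2)^{-1/2} exp(-(log z - alpha_0 - alpha_X' x)^2
                                           / (2 sigma_Z^2)),

evaluated on the log scale.  Note this is the density of log Z evaluated at
log z (no 1/z change-of-variables factor); since the GPS enters the method
only through its value and any strictly monotone transformation preserves
the balancing property, we keep this scale throughout.  The "actual GPS"
R_i is r evaluated at the observed exposure of day i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

from .basis import RegressionSpline, calendar_spline, cubic_quantile_spline
from .data import StudyTimeSeries

__all__ = ["ExposureModel", "ExposureResults", "build_exposure_design", "DomainError", "FitError"]

CAL_DF_PER_YEAR = 5
TEMP_SPLINE_DF = 5


class DomainError(ValueError):
    """Exposure values outside the model's domain (z must be positive)."""


class FitError(RuntimeError):
    """The exposure design cannot be fitted (rank deficiency etc.)."""


def build_exposure_design(
    series: StudyTimeSeries,
) -> tuple[np.ndarray, list, dict]:
    """Assemble the exposure-model covariate matrix for the analysable days.

    Returns ``(X, names, meta)`` where ``meta`` carries the fitted spline
    objects so the same transform can be re-applied.  Column count is
    ``6 + 1 + 1 + 5*years + 5 + 2 + 1``.
    """
    a = series.analysis
    n = series.n
    cols: list[np.ndarray] = []
    names: list[str] = []

    dow = a["dow"].to_numpy()
    for d, lab in enumerate(("tue", "wed", "thu", "fri", "sat", "sun"), start=1):
        cols.append((dow == d).astype(float))
        names.append(f"dow_{lab}")
    cols.append(a["holiday"].to_numpy(dtype=float))
    names.append("holiday")
    cols.append(a["influenza"].to_numpy(dtype=float))
    names.append("influenza")

    cal_mat, cal_spline = calendar_spline(
        a["day_index"].to_numpy(dtype=float), CAL_DF_PER_YEAR, series.n_years
    )
    cols.extend(cal_mat.T)
    names.extend(f"calendar_{j + 1}" for j in range(cal_mat.shape[1]))

    temp_mat, temp_spline = cubic_quantile_spline(series.temp_lag03, TEMP_SPLINE_DF)
    cols.extend(temp_mat.T)
    names.extend(f"temp03_{j + 1}" for j in range(temp_mat.shape[1]))

    hum = a["humidity"].to_numpy(dtype=float)
    cols.append(hum)
    names.append("humidity")
    cols.append(hum**2)
    names.append("humidity_sq")
    cols.append(a["july_aug"].to_numpy(dtype=float))
    names.append("july_aug")

    X = np.column_stack(cols)
    assert X.shape == (n, len(names))
    meta = {"calendar": cal_spline, "temperature": temp_spline}
    return X, names, meta


def _collinear_columns(design: np.ndarray, names: list) -> list:
    """Name the columns responsible for rank deficiency via pivoted QR."""
    _, rdiag, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rdiag))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if diag.size else []
    return [names[j] for j in np.sort(bad)]


class ExposureModel:
    """OLS model of log-exposure on the covariate design.

    Parameters
    ----------
    z : array_like
        Positive exposure values, one per analysable day.
    exog : ndarray
        Covariate matrix (without intercept; one is added internally).
    exog_names : list of str, optional
    """

    def __init__(self, z, exog, exog_names=None, splines=None):
        z = np.asarray(z, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if np.any(z <= 0) or np.any(~np.isfinite(z)):
            raise DomainError("all exposure values must be strictly positive")
        if exog.ndim != 2 or len(z) != len(exog):
            raise ValueError("exog must be 2-D and aligned with z")
        if len(z) <= exog.shape[1] + 1:
            raise ValueError("need more days than covariates")
        self.z = z
        self.exog = exog
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(exog.shape[1])]
        )
        self.splines = splines or {}

    @classmethod
    def from_series(cls, series: StudyTimeSeries) -> "ExposureModel":
        X, names, meta = build_exposure_design(series)
        return cls(series.z, X, names, splines=meta)

    def fit(self) -> "ExposureResults":
        design = np.column_stack([np.ones(len(self.z)), self.exog])
        names = ["const"] + self.exog_names
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(design, names)
            raise FitError(
                "exposure design is rank deficient; collinear column(s): "
                + ", ".join(bad)
            )
        logz = np.log(self.z)
        params, *_ = np.linalg.lstsq(design, logz, rcond=None)
        fitted = design @ params
        resid = logz - fitted
        sigma = float(np.sqrt(np.mean(resid**2)))  # MLE divisor N
        return ExposureResults(
            model=self,
            params=params,
            param_names=names,
            sigma_z=sigma,
            fitted_log_mean=fitted,
            resid=resid,
        )


@dataclass
class ExposureResults:
    """Fitted log-normal exposure model; evaluates the GPS."""

    model: ExposureModel = field(repr=False)
    params: np.ndarray
    param_names: list
    sigma_z: float
    fitted_log_mean: np.ndarray = field(repr=False)
    resid: np.ndarray = field(repr=False)

    @property
    def alpha0(self) -> float:
        return float(self.params[0])

    @property
    def alpha_x(self) -> np.ndarray:
        return self.params[1:]

    @property
    def nobs(self) -> int:
        return len(self.fitted_log_mean)

    def bse(self) -> np.ndarray:
        """Conventional OLS standard errors (divisor N - p)."""
        design = np.column_stack([np.ones(self.nobs), self.model.exog])
        p = design.shape[1]
        s2 = np.sum(self.resid**2) / (self.nobs - p)
        cov = s2 * np.linalg.inv(design.T @ design)
        return np.sqrt(np.diag(cov))

    # ------------------------------------------------------------------
    # GPS evaluation
    # ------------------------------------------------------------------
    def _normal_density(self, logz, mean):
        s2 = self.sigma_z**2
        return np.exp(-((logz - mean) ** 2) / (2.0 * s2)) / np.sqrt(2.0 * np.pi * s2)

    def gps_density(self, z, x_row=None, log_mean=None):
        """GPS r(z; x): conditional density at exposure ``z``.

        Provide either a covariate row ``x_row`` (aligned with the design,
        no intercept) or a precomputed linear predictor ``log_mean``.
        """
        z = np.asarray(z, dtype=float)
        if np.any(z <= 0):
            raise DomainError("z must be strictly positive")
        if log_mean is None:
            if x_row is None:
                raise ValueError("provide x_row or log_mean")
            x_row = np.asarray(x_row, dtype=float)
            log_mean = self.alpha0 + x_row @ self.alpha_x
        return self._normal_density(np.log(z), log_mean)

    def gps_at(self, z) -> np.ndarray:
        """GPS of every training day evaluated at a common exposure ``z``."""
        if z <= 0:
            raise DomainError("z must be strictly positive")
        return self._normal_density(np.log(z), self.fitted_log_mean)

    def actual_gps(self) -> np.ndarray:
        """R_i: the GPS at each day's observed exposure (all positive)."""
        return self._normal_density(np.log(self.model.z), self.fitted_log_mean)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Log-normal exposure model (OLS on log Z)", "-" * 44]
        lines.append(f"{'n days':<22}{self.nobs}")
        lines.append(f"{'sigma_Z (MLE)':<22}{self.sigma_z:.4f}")
        lines.append("-" * 44)
        se = self.bse()
        lines.append(f"{'term':<16}{'coef':>12}{'se':>12}")
        for name, b, s in zip(self.param_names, self.params, se):
            lines.append(f"{name:<16}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)

    def to_text(self) -> str:
        """Serialize coefficients and scale for reuse."""
        body = "\n".join(
            f"{n} {v:.12g}" for n, v in zip(self.param_names, self.params)
        )
        return f"sigma_z {self.sigma_z:.12g}\n{body}"
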