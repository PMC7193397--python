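"""Penalized radial-spline quasi-Poisson model for daily death counts.

The outcome model is

    Y_i(z) ~ quasi-Poisson(lambda_i),  log(lambda_i) = s(z, r(z; X_i)),

where ``s`` is a bivariate smooth of the exposure and the GPS, built from
the low-rank thin-plate basis of :mod:`gpsdrf.basis`.  Fitting is by
penalized iteratively reweighted least squares (P-IRLS) minimizing

    deviance(beta) + lambda * ||radial coefficients||^2 ,

with the smoothing parameter chosen by generalized cross-validation
(n * deviance / (n - edf)^2, edf the trace of the influence matrix at the
final IRLS step) over a logarithmic grid followed by a golden-section
refinement.  The quasi-Poisson dispersion (Pearson chi^2 / (n - edf))
rescales uncertainty only; point estimates coincide with Poisson maximum
penalized likelihood.

Counterfactual prediction standardizes (z, r) by the training min/max and
clamps each coordinate into [0, 1]: a GPS evaluated at a far-away exposure
can leave the training cloud, and clamping bounds the extrapolation (the
number of clamped evaluations is reported and logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .basis import PenalizedBasis, gcv_score, radial_penalized_basis
from .exposure import ExposureResults

__all__ = ["GPSOutcomeModel", "GPSOutcomeResults", "DEFAULT_LAMBDA_GRID", "FitError"]

logger = logging.getLogger(__name__)

#: 40-point logarithmic grid for the smoothing-parameter search.
DEFAULT_LAMBDA_GRID = np.logspace(-6, 6, 40)

_ETA_CLIP = 30.0  # guards exp() during IRLS
_IRLS_TOL = 1e-8
_IRLS_MAXIT = 100

#: Optional degrees-of-freedom inflation applied when *selecting* the
#: smoothing parameter (gamma > 1 charges each effective degree of freedom
#: more, guarding against GCV undersmoothing); 1.0 reproduces plain GCV.
GCV_GAMMA = 1.0


class FitError(RuntimeError):
    """P-IRLS failed to converge or the design is unusable."""


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


class GPSOutcomeModel:
    """Quasi-Poisson dose-response outcome model given exposure and GPS.

    Parameters
    ----------
    counts : array_like
        Non-negative integer daily death counts.
    exposure : array_like
        Lag 0-1 exposure Z_i.
    gps : array_like
        Actual GPS R_i (strictly positive).
    n_knots : int
        Number of radial knots K for the bivariate basis.
    """

    def __init__(self, counts, exposure, gps, n_knots: int = 50):
        y = np.asarray(counts, dtype=float)
        z = np.asarray(exposure, dtype=float)
        r = np.asarray(gps, dtype=float)
        if not (len(y) == len(z) == len(r)):
            raise ValueError("counts, exposure and gps must be aligned")
        if np.any(y < 0) or np.any(y != np.rint(y)):
            raise ValueError("counts must be non-negative integers")
        if np.any(r <= 0):
            raise ValueError("all GPS values must be strictly positive")
        self.y = y
        self.z = z
        self.r = r
        self.n_knots = n_knots
        self.basis: PenalizedBasis = radial_penalized_basis(z, r, n_knots)

    # ------------------------------------------------------------------
    def _pirls(self, lam: float, eta0: np.ndarray | None = None):
        """One penalized IRLS run at fixed smoothing ``lam``."""
        X = self.basis.design
        P = self.basis.penalty
        y = self.y
        n = len(y)
        eta = np.log(y + 0.5) if eta0 is None else eta0.copy()
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        dev = np.inf
        A = None
        for it in range(_IRLS_MAXIT):
            mu = np.exp(eta)
            w = mu  # Poisson log-link working weights
            zwork = eta + (y - mu) / mu
            Xw = X * w[:, None]
            A = X.T @ Xw
            b = Xw.T @ zwork
            try:
                beta = np.linalg.solve(A + lam * P, b)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise FitError(f"singular system at lambda={lam:g}") from exc
            eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
            new_dev = _poisson_deviance(y, np.exp(eta))
            if not np.isfinite(new_dev):
                raise FitError(
                    f"IRLS diverged at lambda={lam:g}, iteration {it}: "
                    f"deviance={new_dev}"
                )
            if abs(dev - new_dev) <= _IRLS_TOL * (abs(new_dev) + 1e-3):
                dev = new_dev
                break
            dev = new_dev
        else:
            raise FitError(
                f"IRLS did not converge in {_IRLS_MAXIT} iterations at "
                f"lambda={lam:g} (deviance trace ends at {dev:.6g})"
            )
        edf = float(np.trace(np.linalg.solve(A + lam * P, A)))
        return {"beta": beta, "eta": eta, "deviance": dev, "edf": edf,
                "gcv": gcv_score(dev, n, edf),
                "gcv_sel": gcv_score(dev, n, min(GCV_GAMMA * edf, n * 0.99)),
                "n_iter": it + 1}

    def fit(
        self,
        smooth: float | None = None,
        lambda_grid=None,
        refine: bool = True,
    ) -> "GPSOutcomeResults":
        """Fit the model; choose the smoothing parameter by GCV.

        Parameters
        ----------
        smooth : float, optional
            Fix the smoothing parameter instead of selecting it.
        lambda_grid : array_like, optional
            Candidate grid (default: 40 log-spaced points in [1e-6, 1e6]).
        refine : bool
            Golden-section refinement of log-lambda around the grid
            minimizer.
        """
        if smooth is not None:
            best = self._pirls(float(smooth))
            lam = float(smooth)
        else:
            grid = np.asarray(
                DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, float
            )
            fits = []
            eta = None
            for lam_g in grid:
                f = self._pirls(lam_g, eta0=eta)
                eta = f["eta"]
                fits.append(f)
            i_best = int(np.argmin([f["gcv_sel"] for f in fits]))
            lam, best = float(grid[i_best]), fits[i_best]
            if refine and 0 < i_best < len(grid) - 1:
                lam, best = self._golden_section(
                    math.log(grid[i_best - 1]),
                    math.log(grid[i_best + 1]),
                    best,
                    math.log(lam),
                )
        mu = np.exp(best["eta"])
        pearson = float(np.sum((self.y - mu) ** 2 / mu))
        dispersion = pearson / (len(self.y) - best["edf"])
        return GPSOutcomeResults(
            model=self,
            basis=self.basis,
            beta=best["beta"],
            lambda_smooth=lam,
            dispersion=dispersion,
            edf=best["edf"],
            deviance=best["deviance"],
            gcv=best["gcv"],
            fittedvalues=mu,
        )

    def _golden_section(self, lo, hi, best, log_best, tol=0.05, max_iter=25):
        """Minimize GCV over log-lambda in [lo, hi] by golden section."""
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = self._pirls(math.exp(c), eta0=best["eta"])
        fd = self._pirls(math.exp(d), eta0=best["eta"])
        for _ in range(max_iter):
            if b - a < tol:
                break
            if fc["gcv_sel"] < fd["gcv_sel"]:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = self._pirls(math.exp(c), eta0=fd["eta"])
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = self._pirls(math.exp(d), eta0=fc["eta"])
        cands = [(best["gcv_sel"], log_best, best),
                 (fc["gcv_sel"], c, fc), (fd["gcv_sel"], d, fd)]
        g, loglam, f = min(cands, key=lambda t: t[0])
        return math.exp(loglam), f


@dataclass
class GPSOutcomeResults:
    """Fitted outcome model; predicts potential outcomes Y_i(z)."""

    model: GPSOutcomeModel = field(repr=False)
    basis: PenalizedBasis = field(repr=False)
    beta: np.ndarray
    lambda_smooth: float
    dispersion: float
    edf: float
    deviance: float
    gcv: float
    fittedvalues: np.ndarray = field(repr=False)
    clamp_events: int = 0

    @property
    def nobs(self) -> int:
        return len(self.fittedvalues)

    @property
    def training_ranges(self) -> dict:
        return {"z": self.basis.z_range, "r": self.basis.r_range}

    def predict_potential(
        self,
        gps_results: ExposureResults,
        z: float,
        return_clamped: bool = False,
    ):
        """Predicted potential outcome Yhat_i(z) for every training day.

        For each day the GPS is re-evaluated at the counterfactual exposure
        ``z``; the pair (z, r(z; X_i)) is standardized by the training
        ranges, clamped into [0, 1]^2, and pushed through the fitted
        surface.
        """
        if z <= 0:
            raise ValueError("z must be strictly positive")
        rhat = gps_results.gps_at(z)
        rows, n_clamped = self.basis.evaluate(np.full(len(rhat), float(z)), rhat)
        if n_clamped:
            logger.debug("predict_potential(z=%.3g): clamped %d of %d days",
                         z, n_clamped, len(rhat))
            self.clamp_events += n_clamped
        yhat = np.exp(np.clip(rows @ self.beta, -_ETA_CLIP, _ETA_CLIP))
        if return_clamped:
            return yhat, n_clamped
        return yhat

    def summary(self) -> str:
        lines = [
            "Penalized radial-spline quasi-Poisson outcome model",
            "-" * 52,
            f"{'n days':<26}{self.nobs}",
            f"{'radial knots (K)':<26}{self.basis.n_knots}",
            f"{'smoothing lambda (GCV)':<26}{self.lambda_smooth:.4g}",
            f"{'effective df':<26}{self.edf:.2f}",
            f"{'deviance':<26}{self.deviance:.2f}",
            f"{'dispersion (Pearson)':<26}{self.dispersion:.3f}",
            f"{'clamped predictions':<26}{self.clamp_events}",
        ]
        return "\n".join(lines)
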