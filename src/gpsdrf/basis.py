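"""Spline design components.

Three kinds of basis are used by the exposure and outcome models:

* a degree-1 (piecewise linear) regression spline on the calendar day with
  equally spaced knots, for seasonality and long-term trend;
* a cubic regression spline with interior knots at quantiles, for
  temperature at lag 0-3;
* a low-rank bivariate thin-plate radial basis on the standardized
  (exposure, GPS) plane with a ridge penalty on the radial block, for the
  outcome surface ``s(z, r)``.

The radial construction follows the usual low-rank smoother recipe: knots
are a deterministic space-filling subset of the observed points, the raw
radial columns phi(||u - kappa_k||) with phi(d) = d^2 log d are
post-multiplied by Omega^{-1/2} (Omega the inter-knot kernel matrix) so
that the roughness penalty becomes the identity on the radial coefficients
and zero on the unpenalized polynomial block [1, z~, r~].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.spatial.distance import cdist

__all__ = [
    "BasisSpec",
    "RegressionSpline",
    "PenalizedBasis",
    "calendar_spline",
    "cubic_quantile_spline",
    "radial_penalized_basis",
    "thin_plate",
    "gcv_score",
]


class DegenerateInputError(ValueError):
    """Input has no usable variation (e.g. a constant covariate)."""


@dataclass(frozen=True)
class BasisSpec:
    """Plain-text-serializable description of a basis, for reproducibility."""

    kind: str  # calendar_linear | cubic_quantile | radial_bivariate
    df: int
    knots: tuple
    scaling: tuple  # per-dimension (min, max) used to standardize inputs

    def to_text(self) -> str:
        lines = [
            f"kind: {self.kind}",
            f"df: {self.df}",
            "knots: " + " ".join(
                ",".join(f"{c:.10g}" for c in np.atleast_1d(k)) for k in self.knots
            ),
            "scaling: " + " ".join(
                f"{lo:.10g},{hi:.10g}" for lo, hi in self.scaling
            ),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# 1-D regression splines
# ----------------------------------------------------------------------
@dataclass
class RegressionSpline:
    """A fitted-scale 1-D spline block that can be re-evaluated at new points.

    ``mode`` controls how the full B-spline basis is made identifiable in a
    design that also carries an intercept:

    * ``drop_first`` -- drop the first B-spline column (the basis sums to
      one, so the span together with an intercept is unchanged while the
      constant leaves the block's own span).
    """

    knot_vector: np.ndarray
    degree: int
    mode: str
    spec: BasisSpec = field(repr=False, default=None)

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knot_vector
        lo, hi = t[self.degree], t[-self.degree - 1]
        xc = np.clip(x, lo, hi)
        full = BSpline.design_matrix(xc, t, self.degree, extrapolate=False).toarray()
        if self.mode == "drop_first":
            return full[:, 1:]
        raise ValueError(f"unknown mode {self.mode!r}")


def _knot_vector(lo: float, hi: float, interior: np.ndarray, degree: int) -> np.ndarray:
    return np.concatenate(
        [np.full(degree + 1, lo), np.asarray(interior, float), np.full(degree + 1, hi)]
    )


def calendar_spline(
    day_index, df_per_year: int, n_years: float
) -> tuple[np.ndarray, RegressionSpline]:
    """Piecewise-linear seasonality spline with equally spaced knots.

    Returns ``df_per_year * n_years`` columns (intercept excluded) built
    from a degree-1 B-spline with ``df - 1`` equally spaced interior knots
    over the observed day range.  Together with an intercept the block
    reproduces exactly any piecewise-linear function breaking at the knots.
    """
    day_index = np.asarray(day_index, dtype=float)
    if df_per_year < 1:
        raise ValueError("df_per_year must be >= 1")
    df = int(round(df_per_year * n_years))
    if df < 1:
        raise ValueError("total degrees of freedom must be >= 1")
    if df + 1 > np.unique(day_index).size:
        raise ValueError(
            f"df={df} too large for {np.unique(day_index).size} distinct days"
        )
    lo, hi = day_index.min(), day_index.max()
    interior = np.linspace(lo, hi, df + 1)[1:-1]  # df - 1 interior knots
    t = _knot_vector(lo, hi, interior, 1)
    spec = BasisSpec("calendar_linear", df, tuple(interior), ((lo, hi),))
    spline = RegressionSpline(t, 1, "drop_first", spec)
    return spline.evaluate(day_index), spline


def cubic_quantile_spline(x, df: int) -> tuple[np.ndarray, RegressionSpline]:
    """Cubic regression spline with interior knots at quantiles.

    Returns ``df`` columns (constant excluded from the span, so the block
    stays full rank alongside an intercept) with ``df - 3`` interior knots
    at equally spaced quantiles of ``x``.  Together with an intercept the
    block spans the full cubic spline space on those knots; in particular
    any cubic polynomial is reproduced exactly for every ``df >= 4``.
    """
    x = np.asarray(x, dtype=float)
    if df < 4:
        raise ValueError("df must be >= 4 for a cubic basis")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; cannot build a spline basis")
    m = df - 3
    lo, hi = x.min(), x.max()
    qs = np.arange(1, m + 1) / (m + 1)
    interior = np.quantile(x, qs)
    if np.unique(interior).size != m or interior.min() <= lo or interior.max() >= hi:
        raise DegenerateInputError(
            "quantile knots are tied or touch the boundary; reduce df"
        )
    t = _knot_vector(lo, hi, interior, 3)
    spec = BasisSpec("cubic_quantile", df, tuple(interior), ((lo, hi),))
    spline = RegressionSpline(t, 3, "drop_first", spec)
    return spline.evaluate(x), spline


# ----------------------------------------------------------------------
# bivariate thin-plate radial basis
# ----------------------------------------------------------------------
def thin_plate(d) -> np.ndarray:
    """2-D thin-plate kernel phi(d) = d^2 log d, with phi(0) = 0."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    dp = d[pos]
    out[pos] = dp * dp * np.log(dp)
    return out


def _greedy_maxmin(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling design: seed at the point nearest the
    centroid, then repeatedly add the point farthest from the chosen set.

    Operates on (lexicographically sorted) unique points, so the result is
    invariant to the ordering of the input rows.  Ties break to the lowest
    index, hence no RNG is involved.
    """
    uq = np.unique(points, axis=0)
    if k > len(uq):
        raise ValueError(f"K={k} exceeds the number of distinct points ({len(uq)})")
    centroid = points.mean(axis=0)
    start = int(np.argmin(np.linalg.norm(uq - centroid, axis=1)))
    chosen = [start]
    mind = np.linalg.norm(uq - uq[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(uq - uq[nxt], axis=1))
    return uq[chosen]


@dataclass
class PenalizedBasis:
    """Low-rank thin-plate design over standardized (exposure, GPS) space.

    ``design`` stacks the unpenalized polynomial block ``[1, z~, r~]`` and
    K transformed radial columns; ``penalty`` is the (3+K) x (3+K) matrix
    acting as the identity on the radial block and zero on the polynomial
    block.
    """

    knots_std: np.ndarray  # (K, 2) in standardized space
    z_range: tuple
    r_range: tuple
    omega_inv_sqrt: np.ndarray  # (K, K)
    design: np.ndarray  # (N, 3+K) at the training points
    penalty: np.ndarray

    @property
    def n_knots(self) -> int:
        return len(self.knots_std)

    def _standardize(self, z, r, clamp: bool):
        z = np.asarray(z, dtype=float)
        r = np.asarray(r, dtype=float)
        zt = (z - self.z_range[0]) / (self.z_range[1] - self.z_range[0])
        rt = (r - self.r_range[0]) / (self.r_range[1] - self.r_range[0])
        n_clamped = 0
        if clamp:
            out = (zt < 0) | (zt > 1) | (rt < 0) | (rt > 1)
            n_clamped = int(np.count_nonzero(out))
            zt = np.clip(zt, 0.0, 1.0)
            rt = np.clip(rt, 0.0, 1.0)
        return zt, rt, n_clamped

    def evaluate(self, z, r, clamp: bool = True) -> tuple[np.ndarray, int]:
        """Design rows at new (z, r) points; returns (rows, n_clamped)."""
        zt, rt, n_clamped = self._standardize(z, r, clamp)
        pts = np.column_stack([zt, rt])
        radial = thin_plate(cdist(pts, self.knots_std)) @ self.omega_inv_sqrt
        rows = np.column_stack([np.ones(len(pts)), zt, rt, radial])
        return rows, n_clamped

    @property
    def spec(self) -> BasisSpec:
        return BasisSpec(
            "radial_bivariate",
            self.design.shape[1],
            tuple(map(tuple, self.knots_std)),
            (self.z_range, self.r_range),
        )


#: Floor applied to the eigenvalues of the inter-knot kernel matrix before
#: forming Omega^{-1/2}; keeps the transform well-conditioned.
EIGENVALUE_FLOOR = 1e-8


def radial_penalized_basis(z, r, n_knots: int = 50) -> PenalizedBasis:
    """Build the penalized bivariate radial basis on observed (z, r) pairs.

    Steps: min-max standardize both coordinates to [0, 1] (exposure and GPS
    live on incommensurate scales); choose ``n_knots`` knots among the
    observed points by the deterministic greedy max-min design; evaluate
    phi(d) = d^2 log d at distances to the knots; and absorb the kernel
    matrix so the penalty is the identity on the radial block.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.shape != r.shape or z.ndim != 1:
        raise ValueError("z and r must be 1-D arrays of equal length")
    if n_knots < 4:
        raise ValueError("need at least 4 radial knots")
    if len(z) <= n_knots:
        raise ValueError("need more observations than knots")
    if np.ptp(z) == 0 or np.ptp(r) == 0:
        raise DegenerateInputError("z and r must each have positive range")

    z_range = (float(z.min()), float(z.max()))
    r_range = (float(r.min()), float(r.max()))
    zt = (z - z_range[0]) / (z_range[1] - z_range[0])
    rt = (r - r_range[0]) / (r_range[1] - r_range[0])
    pts = np.column_stack([zt, rt])
    knots = _greedy_maxmin(pts, n_knots)

    omega = thin_plate(cdist(knots, knots))
    omega = 0.5 * (omega + omega.T)
    w, v = np.linalg.eigh(omega)
    w = np.maximum(np.abs(w), EIGENVALUE_FLOOR)
    omega_inv_sqrt = (v / np.sqrt(w)) @ v.T

    radial = thin_plate(cdist(pts, knots)) @ omega_inv_sqrt
    design = np.column_stack([np.ones(len(z)), zt, rt, radial])
    penalty = np.zeros((3 + n_knots, 3 + n_knots))
    penalty[3:, 3:] = np.eye(n_knots)
    return PenalizedBasis(knots, z_range, r_range, omega_inv_sqrt, design, penalty)


def gcv_score(deviance: float, n: int, edf: float) -> float:
    """Generalized cross-validation score ``n * deviance / (n - edf)^2``."""
    if not 0 <= edf < n:
        raise ValueError(f"edf must lie in [0, n); got edf={edf}, n={n}")
    return n * deviance / (n - edf) ** 2
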