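"""Covariate-balance diagnostics for the generalized propensity score.

The GPS is a balancing score: within strata of days sharing the same
r(z; x), the exposure level is independent of the covariates.  Following
the Hirano-Imbens blocking check, days are grouped into four exposure
classes

    C1 = (0, 20), C2 = [20, 40), C3 = [40, 70), C4 = [70, +inf)

(micrograms per m^3), and for each covariate and class we compare

* the *marginal* t statistic for the mean difference between days in the
  class and all other days, and
* the *GPS-adjusted* t statistic: the GPS is evaluated for every day at
  the class median exposure M_k, days are blocked by the quartiles of
  r(M_k; X_i), within-block Welch mean differences are combined with
  weights proportional to block size, and the combined difference is
  divided by its standard error sqrt(sum w_j^2 se_j^2).

If the exposure model is adequate, the adjusted statistics shrink toward
zero relative to the marginal ones, most visibly where the raw imbalance
is strong.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .data import StudyTimeSeries
from .exposure import ExposureResults

__all__ = [
    "EXPOSURE_CLASS_EDGES",
    "exposure_class",
    "marginal_t",
    "gps_adjusted_t",
    "balance_report",
    "default_balance_covariates",
    "DegenerateGroupError",
    "BalanceUndefinedError",
]

logger = logging.getLogger(__name__)

#: Right-open exposure class edges in micrograms per m^3.
EXPOSURE_CLASS_EDGES = (0.0, 20.0, 40.0, 70.0, math.inf)

CLASS_LABELS = ("(0,20)", "[20,40)", "[40,70)", "[70+)")


class DegenerateGroupError(ValueError):
    """A comparison group has fewer than two members."""


class BalanceUndefinedError(ValueError):
    """No usable block remains for a (covariate, class) pair."""


def exposure_class(z) -> np.ndarray:
    """Class index 0..3 for each exposure value (right-open intervals)."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("exposure values must be positive")
    return np.clip(np.searchsorted(EXPOSURE_CLASS_EDGES[1:-1], z, side="right"), 0, 3)


def _welch_components(x, mask):
    """Mean difference (in - out), its Welch SE, and the group sizes."""
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x1, x0 = x[mask], x[~mask]
    if len(x1) < 2 or len(x0) < 2:
        raise DegenerateGroupError(
            f"groups of sizes {len(x1)} and {len(x0)}; need >= 2 in each"
        )
    diff = x1.mean() - x0.mean()
    se = math.sqrt(x1.var(ddof=1) / len(x1) + x0.var(ddof=1) / len(x0))
    return diff, se, len(x1), len(x0)


def marginal_t(x, in_class) -> float:
    """Welch two-sample t for mean(x | in class) - mean(x | outside).

    Zero-variance groups (SE = 0) are signalled with an infinite sentinel
    (NaN when the difference is also zero) rather than an exception.
    """
    diff, se, *_ = _welch_components(x, in_class)
    if se == 0.0:
        return math.copysign(math.inf, diff) if diff != 0 else math.nan
    return diff / se


def gps_adjusted_t(
    gps_results: ExposureResults,
    series: StudyTimeSeries,
    x,
    k: int,
    n_blocks: int = 4,
) -> tuple[float, int]:
    """GPS-blocked t statistic for covariate ``x`` and exposure class ``k``.

    Returns ``(t, n_blocks_used)``.  Blocks where either side has fewer
    than two days are dropped with a logged warning and the block weights
    renormalized; if every block is degenerate a
    :class:`BalanceUndefinedError` is raised.
    """
    x = np.asarray(x, dtype=float)
    z = series.z
    classes = exposure_class(z)
    in_class = classes == k
    if not in_class.any():
        raise BalanceUndefinedError(f"exposure class {k} is empty")

    m_k = float(np.median(z[in_class]))
    scores = gps_results.gps_at(m_k)  # r(M_k; X_i) for every day
    cuts = np.quantile(scores, np.arange(1, n_blocks) / n_blocks)
    # ties at a quartile boundary fall in the lower block
    block = np.searchsorted(cuts, scores, side="left")

    diffs, ses, sizes = [], [], []
    for j in range(n_blocks):
        sel = block == j
        try:
            d, se, *_ = _welch_components(x[sel], in_class[sel])
        except DegenerateGroupError:
            logger.warning(
                "balance: dropping degenerate block %d for class %s (%d days)",
                j, CLASS_LABELS[k], int(sel.sum()),
            )
            continue
        diffs.append(d)
        ses.append(se)
        sizes.append(int(sel.sum()))
    if not diffs:
        raise BalanceUndefinedError(
            f"all GPS blocks degenerate for class {CLASS_LABELS[k]}"
        )
    w = np.asarray(sizes, dtype=float)
    w /= w.sum()
    diff = float(np.dot(w, diffs))
    se = math.sqrt(float(np.dot(w**2, np.square(ses))))
    if se == 0.0:
        t = math.copysign(math.inf, diff) if diff != 0 else math.nan
    else:
        t = diff / se
    return t, len(diffs)


def default_balance_covariates(series: StudyTimeSeries) -> dict:
    """The covariate set checked in the balance table.

    Temperature at lag 0-3, an extreme-temperature indicator (lag 0-3
    temperature above its 95th percentile), humidity at lag 0, and summer /
    weekend / holiday / influenza indicators.
    """
    a = series.analysis
    t03 = series.temp_lag03
    return {
        "temp_lag03": t03,
        "heat_episode": (t03 > np.percentile(t03, 95)).astype(float),
        "humidity": a["humidity"].to_numpy(dtype=float),
        "summer": a["summer"].to_numpy(dtype=float),
        "weekend": a["weekend"].to_numpy(dtype=float),
        "holiday": a["holiday"].to_numpy(dtype=float),
        "influenza": a["influenza"].to_numpy(dtype=float),
    }


def balance_report(
    gps_results: ExposureResults,
    series: StudyTimeSeries,
    covariates: dict | None = None,
) -> pd.DataFrame:
    """Marginal vs GPS-adjusted t statistics, one row per (covariate, class).

    The ``improved`` column flags rows where |adjusted| < |marginal|;
    degenerate marginal comparisons surface as +/-inf or NaN sentinels.
    """
    if covariates is None:
        covariates = default_balance_covariates(series)
    if not covariates:
        raise ValueError("covariate set must be non-empty")
    classes = exposure_class(series.z)
    rows = []
    for name, x in covariates.items():
        for k in range(4):
            in_class = classes == k
            try:
                mt = marginal_t(x, in_class)
            except DegenerateGroupError:
                mt = math.nan
            try:
                at, nb = gps_adjusted_t(gps_results, series, x, k)
            except (BalanceUndefinedError, DegenerateGroupError):
                at, nb = math.nan, 0
            rows.append(
                {
                    "covariate": name,
                    "exposure_class": CLASS_LABELS[k],
                    "marginal_t": mt,
                    "gps_adjusted_t": at,
                    "n_blocks_used": nb,
                    "improved": abs(at) < abs(mt)
                    if np.isfinite(at) and np.isfinite(mt)
                    else False,
                }
            )
    return pd.DataFrame(rows)
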