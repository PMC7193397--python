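"""Daily time-series data model for short-term air-pollution mortality studies.

The analysis unit is the day.  Each record carries the raw pollutant
concentration, daily death counts by cause, meteorology and calendar
indicators.  From the raw series we derive the two lagged variables the
method works with:

* ``z`` -- the lag 0-1 exposure, the mean of today's and yesterday's
  concentration (micrograms per cubic metre).  Using a short moving average
  instead of the same-day level makes the no-interference (SUTVA)
  assumption behind the potential-outcome notation more plausible.
* ``temp_lag03`` -- mean temperature over lags 0-3 (degrees Celsius), the
  confounder scale on which temperature enters the exposure model.

Days whose lag windows reach before the start of the series are dropped
(never imputed), so a raw series of ``n`` consecutive days yields an
analysis table of ``n - 3`` days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CAUSES",
    "DEFAULT_COLUMNS",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "StudyTimeSeries",
    "compute_lagged",
    "read_timeseries",
    "write_timeseries",
]

#: Causes of death tracked in the analysis table, each with its own count
#: column.  Every downstream estimand is computed per cause independently.
CAUSES = ("natural", "cvd", "resp")

#: Default CSV column names; override any of them through ``column_map``.
DEFAULT_COLUMNS = {
    "date": "date",
    "pm10": "pm10",
    "temp": "temp",
    "humidity": "humidity",
    "holiday": "holiday",
    "influenza": "influenza",
    "deaths_natural": "deaths_natural",
    "deaths_cvd": "deaths_cvd",
    "deaths_resp": "deaths_resp",
}

#: Longest lag window used when deriving variables (temperature lag 0-3).
MAX_LAG = 3


class FormatError(ValueError):
    """The input table does not have the expected columns/shape."""


class IntegrityError(ValueError):
    """Dates are duplicated, unsorted or gapped."""


class ValidationError(ValueError):
    """A value violates a domain constraint (negative count, humidity...)."""


def compute_lagged(series_values, max_lag: int) -> np.ndarray:
    """Moving average of a daily series over lags ``0..max_lag``.

    Element ``i`` of the result is the mean of the values at positions
    ``i, i-1, ..., i-max_lag``; the first ``max_lag`` positions, whose
    windows are incomplete, are NaN.

    Parameters
    ----------
    series_values : array_like
        Daily values, oldest first.
    max_lag : int
        Number of preceding days entering each window (``>= 0``).
    """
    v = np.asarray(series_values, dtype=float)
    if v.ndim != 1:
        raise ValueError("series_values must be one-dimensional")
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    if max_lag >= v.size:
        raise ValueError(
            f"max_lag ({max_lag}) must be smaller than the series length ({v.size})"
        )
    if max_lag == 0:
        return v.copy()
    out = np.full(v.size, np.nan)
    kernel = np.full(max_lag + 1, 1.0 / (max_lag + 1))
    out[max_lag:] = np.convolve(v, kernel, mode="valid")
    return out


def _require_columns(df: pd.DataFrame, colmap: dict) -> None:
    missing = [name for name in colmap.values() if name not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")


@dataclass
class StudyTimeSeries:
    """Validated per-day analysis table with derived lag variables.

    Attributes
    ----------
    raw : pandas.DataFrame
        One row per calendar day (gap-free), standard column names.
    analysis : pandas.DataFrame
        Rows with complete lag windows (the last ``n - 3`` days), augmented
        with ``z``, ``temp_lag03`` and calendar helper columns
        (``dow``, ``weekend``, ``july_aug``, ``summer``, ``day_index``).
    exposure_precomputed : bool
        If True the ``pm10`` column already holds the aggregated (lag 0-1)
        exposure and is used as ``z`` directly; otherwise ``z`` is the mean
        of the current and previous day's ``pm10``.
    """

    raw: pd.DataFrame
    analysis: pd.DataFrame = field(repr=False)
    exposure_precomputed: bool = False

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        column_map: dict | None = None,
        exposure_precomputed: bool = False,
    ) -> "StudyTimeSeries":
        colmap = dict(DEFAULT_COLUMNS)
        if column_map:
            colmap.update(column_map)
        _require_columns(frame, colmap)

        df = pd.DataFrame(
            {std: frame[src].to_numpy() for std, src in colmap.items()}
        )
        df["date"] = pd.to_datetime(df["date"], errors="raise")

        # -- integrity: strictly consecutive calendar days -------------
        dates = df["date"]
        if dates.duplicated().any():
            dup = dates[dates.duplicated()].iloc[0].date()
            raise IntegrityError(f"duplicated date: {dup}")
        deltas = dates.diff().dropna().dt.days.to_numpy()
        if (deltas < 0).any():
            raise IntegrityError("dates are not sorted ascending")
        if (deltas != 1).any():
            i = int(np.argmax(deltas != 1))
            raise IntegrityError(
                f"gap in dates after {dates.iloc[i].date()}; the series must be gap-free"
            )

        # -- domain validation ------------------------------------------
        for cause in CAUSES:
            col = df[f"deaths_{cause}"].to_numpy(dtype=float)
            if np.any(col < 0) or np.any(col != np.rint(col)) or np.any(~np.isfinite(col)):
                raise ValidationError(
                    f"deaths_{cause} must contain non-negative integers"
                )
            df[f"deaths_{cause}"] = col.astype(int)
        pm10 = df["pm10"].to_numpy(dtype=float)
        if np.any(pm10 < 0) or np.any(~np.isfinite(pm10)):
            raise ValidationError("pm10 must be non-negative and finite")
        hum = df["humidity"].to_numpy(dtype=float)
        if np.any((hum < 0) | (hum > 100)):
            raise ValidationError("humidity must lie in [0, 100]")
        for ind in ("holiday", "influenza"):
            v = df[ind].to_numpy(dtype=float)
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValidationError(f"{ind} must be a 0/1 indicator")
            df[ind] = v.astype(int)
        if len(df) <= MAX_LAG:
            raise FormatError(
                f"need more than {MAX_LAG} days to form lagged variables"
            )

        # -- derived lag variables --------------------------------------
        if exposure_precomputed:
            z_full = pm10.astype(float)
        else:
            z_full = compute_lagged(pm10, 1)
        temp_lag03 = compute_lagged(df["temp"].to_numpy(dtype=float), MAX_LAG)

        analysis = df.iloc[MAX_LAG:].reset_index(drop=True).copy()
        analysis["z"] = z_full[MAX_LAG:]
        analysis["temp_lag03"] = temp_lag03[MAX_LAG:]
        analysis["day_index"] = np.arange(MAX_LAG, len(df))
        dow = analysis["date"].dt.dayofweek  # Monday=0
        analysis["dow"] = dow.to_numpy()
        analysis["weekend"] = (dow >= 5).astype(int).to_numpy()
        month = analysis["date"].dt.month.to_numpy()
        analysis["july_aug"] = np.isin(month, (7, 8)).astype(int)
        analysis["summer"] = np.isin(month, (6, 7, 8)).astype(int)

        return cls(raw=df, analysis=analysis, exposure_precomputed=exposure_precomputed)

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of analysable days (complete lag windows)."""
        return len(self.analysis)

    @property
    def n_days(self) -> int:
        """Number of raw calendar days."""
        return len(self.raw)

    @property
    def n_years(self) -> float:
        return self.n_days / 365.25

    @property
    def z(self) -> np.ndarray:
        """Lag 0-1 exposure for analysable days (micrograms per m^3)."""
        return self.analysis["z"].to_numpy(dtype=float)

    @property
    def temp_lag03(self) -> np.ndarray:
        """Mean temperature over lags 0-3 for analysable days (deg C)."""
        return self.analysis["temp_lag03"].to_numpy(dtype=float)

    def deaths(self, cause: str = "natural") -> np.ndarray:
        if cause not in CAUSES:
            raise ValueError(f"unknown cause {cause!r}; expected one of {CAUSES}")
        return self.analysis[f"deaths_{cause}"].to_numpy(dtype=float)

    # ------------------------------------------------------------------
    # output
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Raw daily table plus derived columns (NaN where undefined)."""
        out = self.raw.copy()
        n = len(out)
        z_full = np.full(n, np.nan)
        t_full = np.full(n, np.nan)
        z_full[MAX_LAG:] = self.analysis["z"].to_numpy()
        t_full[MAX_LAG:] = self.analysis["temp_lag03"].to_numpy()
        out["z"] = z_full
        out["temp_lag03"] = t_full
        return out

    def to_csv(self, path) -> None:
        out = self.to_frame()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def read_timeseries(
    path,
    column_map: dict | None = None,
    exposure_precomputed: bool = False,
) -> StudyTimeSeries:
    """Read a daily CSV table and build the validated analysis series.

    The file must have a header, one row per day, ISO-8601 dates sorted
    ascending with no gaps.  Derived columns (``z``, ``temp_lag03``) in the
    file are ignored and recomputed, so write/read round-trips are stable.
    """
    frame = pd.read_csv(path)
    return StudyTimeSeries.from_frame(
        frame, column_map=column_map, exposure_precomputed=exposure_precomputed
    )


def write_timeseries(series: StudyTimeSeries, path) -> None:
    """Write the raw table plus derived exposure columns to CSV."""
    series.to_csv(path)
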