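"""Data model, CSV I/O and lagged-variable construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpsdrf.data import (
    FormatError,
    IntegrityError,
    StudyTimeSeries,
    ValidationError,
    compute_lagged,
    read_timeseries,
    write_timeseries,
)
from gpsdrf.synthetic import GeneratorConfig, generate


def _toy_frame(n=6, pm10=None, **overrides):
    pm10 = list(pm10) if pm10 is not None else [10.0 * (i + 1) for i in range(n)]
    n = len(pm10)
    base = {
        "date": pd.date_range("2003-01-01", periods=n).strftime("%Y-%m-%d"),
        "pm10": pm10,
        "temp": np.linspace(0.0, 10.0, n),
        "humidity": [60.0] * n,
        "holiday": [0] * n,
        "influenza": [0] * n,
        "deaths_natural": [20] * n,
        "deaths_cvd": [8] * n,
        "deaths_resp": [2] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestComputeLagged:
    @pytest.mark.parametrize(
        "values, max_lag, pos, expected",
        [
            ([0.0, 10.0, 20.0, 30.0], 3, 3, 15.0),  # mean of the 4 values
            ([10.0, 30.0, 50.0, 70.0], 1, 1, 20.0),  # adjacent-day mean
            ([10.0, 30.0, 50.0, 70.0], 1, 3, 60.0),
        ],
    )
    def test_window_means(self, values, max_lag, pos, expected):
        out = compute_lagged(values, max_lag)
        assert out[pos] == pytest.approx(expected)
        assert np.isnan(out[:max_lag]).all()

    def test_lag_zero_is_identity(self):
        v = np.array([3.0, 1.0, 4.0, 1.5])
        assert np.array_equal(compute_lagged(v, 0), v)

    def test_lag_one_equals_adjacent_mean(self, rng):
        v = rng.normal(size=50)
        out = compute_lagged(v, 1)
        assert np.allclose(out[1:], (v[1:] + v[:-1]) / 2.0)

    def test_max_lag_too_large(self):
        with pytest.raises(ValueError, match="max_lag"):
            compute_lagged([1.0, 2.0], 2)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=40),
        st.integers(0, 3),
        st.floats(-10, 10),
    )
    def test_translation_equivariance(self, values, max_lag, c):
        """Adding a constant shifts every defined output by that constant."""
        v = np.asarray(values)
        a = compute_lagged(v, max_lag)
        b = compute_lagged(v + c, max_lag)
        assert np.allclose(a[max_lag:] + c, b[max_lag:], atol=1e-9)


class TestStudyTimeSeries:
    def test_lag01_exposure_arithmetic(self):
        s = StudyTimeSeries.from_frame(_toy_frame(pm10=[10, 30, 50, 70, 90]))
        # analysable days start at index 3; z_i = (pm10_i + pm10_{i-1})/2
        assert np.allclose(s.z, [60.0, 80.0])

    def test_missing_column_named_in_error(self):
        frame = _toy_frame().drop(columns=["humidity"])
        with pytest.raises(FormatError, match="humidity"):
            StudyTimeSeries.from_frame(frame)

    def test_gapped_dates_rejected(self):
        frame = _toy_frame()
        dates = pd.to_datetime(frame["date"]).tolist()
        dates[-1] += pd.Timedelta(days=5)
        frame["date"] = [d.strftime("%Y-%m-%d") for d in dates]
        with pytest.raises(IntegrityError, match="gap"):
            StudyTimeSeries.from_frame(frame)

    def test_duplicated_date_rejected(self):
        frame = _toy_frame()
        frame.loc[1, "date"] = frame.loc[0, "date"]
        with pytest.raises(IntegrityError):
            StudyTimeSeries.from_frame(frame)

    @pytest.mark.parametrize(
        "column, bad",
        [
            ("deaths_natural", -1),
            ("deaths_resp", 2.5),
            ("pm10", -3.0),
            ("humidity", 140.0),
            ("holiday", 2),
        ],
    )
    def test_domain_validation(self, column, bad):
        frame = _toy_frame()
        frame[column] = frame[column].astype(float)
        frame.loc[2, column] = bad
        with pytest.raises(ValidationError):
            StudyTimeSeries.from_frame(frame)

    def test_column_map_renames(self):
        frame = _toy_frame().rename(columns={"pm10": "conc"})
        s = StudyTimeSeries.from_frame(frame, column_map={"pm10": "conc"})
        assert s.n == len(frame) - 3

    def test_dropping_leading_days_preserves_lags(self):
        """Retained lag values never depend on how many early days exist."""
        frame = _toy_frame(n=12)
        full = StudyTimeSeries.from_frame(frame)
        # same frame minus its first day: overlapping days must agree
        sub = StudyTimeSeries.from_frame(frame.iloc[1:].reset_index(drop=True))
        assert np.allclose(full.z[1:], sub.z)
        assert np.allclose(full.temp_lag03[1:], sub.temp_lag03)


class TestRoundTrip:
    def test_write_read_identity_synthetic(self, tmp_path):
        series, _ = generate(GeneratorConfig(seed=5, n_days=1461))
        path = tmp_path / "study.csv"
        write_timeseries(series, path)
        back = read_timeseries(path, exposure_precomputed=True)
        for col in ("pm10", "temp", "humidity", "holiday", "influenza",
                    "deaths_natural", "deaths_cvd", "deaths_resp"):
            assert np.allclose(
                series.raw[col].to_numpy(dtype=float),
                back.raw[col].to_numpy(dtype=float),
            ), col
        assert np.allclose(series.z, back.z)
        assert np.allclose(series.temp_lag03, back.temp_lag03)

    def test_derived_columns_recomputed_not_trusted(self, tmp_path):
        series = StudyTimeSeries.from_frame(_toy_frame(n=8))
        path = tmp_path / "t.csv"
        series.to_csv(path)
        frame = pd.read_csv(path)
        frame["z"] = -999.0  # corrupt the derived column
        frame.to_csv(path, index=False)
        back = read_timeseries(path)
        assert np.allclose(back.z, series.z)
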