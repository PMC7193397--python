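"""Synthetic daily time series with known ground-truth estimands.

The generator emulates the statistical structure of a four-year urban
air-pollution mortality study: a winter-peaking pollutant whose (lag 0-1)
exposure is log-normal given season, temperature and weekday; seasonal
temperature and humidity; calendar indicators; and per-cause Poisson death
counts whose log-mean combines a seasonal/temperature baseline with a
known saturating dose-response

    g(z) = gamma * log(1 + z / tau),

steep at low concentrations and flattening above a few tens of
micrograms per m^3.  Because exposure and mortality share the seasonal and
temperature drivers, the exposure-outcome association is confounded by
construction and naive marginal contrasts are biased.

The exposure is drawn directly at the analysis (lag 0-1) level, i.i.d.
log-normal given the same day's covariates, so the data exactly satisfy
the model the GPS method assumes; the stored pollutant column therefore
already holds the aggregated exposure (``exposure_precomputed=True`` in
:mod:`gpsdrf.data`).  The generator exposes exact per-day expected
potential outcomes, hence closed-form true values of the aDRF, AD and DAD
for any threshold, against which estimates can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MAX_LAG, StudyTimeSeries

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "true_estimands"]

_HOLIDAYS = (
    (1, 1), (1, 6), (4, 25), (5, 1), (6, 2),
    (8, 15), (11, 1), (12, 8), (12, 25), (12, 26),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults are calibrated to a polluted mid-latitude city: marginal PM10 mean
    ~52.5 and SD ~33 micrograms/m^3, temperature mean 14.5 and SD ~8.4 deg
    C, and mean daily deaths ~28.0 (natural), 10.3 (cardiovascular) and
    2.5 (respiratory).
    """

    n_days: int = 1461
    seed: int = 0
    start: str = "2003-01-01"
    # temperature: sinusoid peaking in late July plus i.i.d. noise (deg C)
    temp_mean: float = 14.5
    temp_amplitude: float = 10.0
    temp_sd: float = 3.0
    temp_phase_day: int = 28  # seasonal peak at day-of-year 28 + 365/2
    temp_ar: float = 0.0  # optional AR(1) coefficient for the noise
    # humidity: winter-peaking sinusoid, clipped to [20, 100] (%)
    humidity_mean: float = 65.0
    humidity_amplitude: float = 15.0
    humidity_sd: float = 8.0
    # exposure: log Z = alpha0 + seasonal + temperature + weekend + noise
    alpha0: float = 3.82
    seasonal_coef: float = 0.036  # loading on the winter(+1)/summer(-1) wave
    temp_coef: float = -0.0024  # per deg C beyond the shared seasonal wave
    weekend_coef: float = -0.08
    sigma_z: float = 0.575
    exposure_tail_cut: float = 2.8  # exposure residual truncation (sigma units)
    # outcome: log lambda = baseline + winter wave + temperature U + g(Z)
    baseline_mean: dict = field(
        default_factory=lambda: {"natural": 28.0, "cvd": 10.3, "resp": 2.5}
    )
    winter_mort_coef: float = 0.02
    temp_mort_quad: float = 0.0001  # per (deg C)^2 away from the optimum
    temp_mort_ref: float = 20.0
    gamma: float = 0.13  # dose-response scale
    tau: float = 20.0  # dose-response saturation (micrograms/m^3)
    interaction: float = 0.0  # exposure x temperature synergy, per deg C
    overdispersion: float = 0.0  # gamma-frailty variance (0 = pure Poisson)

    def validate(self) -> None:
        if self.n_days <= MAX_LAG:
            raise ValueError("n_days too small")
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be positive")
        if self.gamma < 0 or self.tau <= 0:
            raise ValueError("need gamma >= 0 and tau > 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _dose_response(z, cfg: GeneratorConfig):
    return cfg.gamma * np.log1p(np.asarray(z, dtype=float) / cfg.tau)


@dataclass
class SyntheticTruth:
    """Exact expected potential outcomes of a generated series.

    ``eta0`` holds, per cause, the log baseline (everything except the
    dose-response term) for each analysable day, so that

        E[Y_i(z)] = exp(eta0_i + g(z) * (1 + interaction * (T_i - Tbar))).
    """

    config: GeneratorConfig
    z: np.ndarray = field(repr=False)
    temp: np.ndarray = field(repr=False)
    eta0: dict = field(repr=False)
    winter_wave: np.ndarray = field(repr=False, default=None)
    weekend: np.ndarray = field(repr=False, default=None)

    def exposure_truth(self):
        """The generating exposure design and its coefficients.

        Returns ``(X, alpha, sigma_z)`` where ``X`` (analysable days x 3)
        holds the winter wave, centred temperature and weekend indicator,
        and ``alpha`` is (intercept, seasonal, temperature, weekend).
        Fitting log Z on [1, X] is a correctly specified regression, so
        estimates are unbiased for ``alpha`` and sigma_hat for sigma_z.
        """
        cfg = self.config
        X = np.column_stack(
            [self.winter_wave, self.temp - cfg.temp_mean, self.weekend]
        )
        alpha = np.array(
            [cfg.alpha0, cfg.seasonal_coef, cfg.temp_coef, cfg.weekend_coef]
        )
        return X, alpha, self.sigma_z_effective

    @property
    def sigma_z_effective(self) -> float:
        """Residual SD of log Z implied by the truncated noise law."""
        from scipy.stats import truncnorm

        c = self.config.exposure_tail_cut
        if c <= 0:
            return self.config.sigma_z
        return float(self.config.sigma_z * truncnorm.std(-c, c))

    def _effect_scale(self):
        return 1.0 + self.config.interaction * (self.temp - self.config.temp_mean)

    def expected_potential(self, z_value: float, cause: str = "natural") -> np.ndarray:
        """E[Y_i(z)] for every analysable day."""
        g = _dose_response(z_value, self.config)
        return np.exp(self.eta0[cause] + g * self._effect_scale())

    def expected_observed(self, cause: str = "natural") -> np.ndarray:
        g = _dose_response(self.z, self.config)
        return np.exp(self.eta0[cause] + g * self._effect_scale())

    def mu(self, z_value: float, cause: str = "natural", subset_mask=None) -> float:
        """True aDRF mu(z) (optionally over a subset of days)."""
        ey = self.expected_potential(z_value, cause)
        if subset_mask is not None:
            ey = ey[np.asarray(subset_mask, dtype=bool)]
        return float(ey.mean())

    def ad(self, z_star: float, cause: str = "natural") -> float:
        """True attributable deaths under the fixed-cap counterfactual."""
        self._check_z_star(z_star)
        treated = self.z > z_star
        if not treated.any():
            return 0.0
        ey_obs = self.expected_observed(cause)[treated]
        ey_cf = self.expected_potential(z_star, cause)[treated]
        return float(np.sum(ey_obs - ey_cf))

    def dad(self, z_star: float, cause: str = "natural") -> float:
        """True distributional attributable deaths, by exact enumeration."""
        self._check_z_star(z_star)
        treated = self.z > z_star
        below = self.z[~treated]
        if not treated.any() or below.size == 0:
            raise ValueError("DAD truth needs days on both sides of z*")
        ey_obs_sum = float(self.expected_observed(cause)[treated].sum())
        values, counts = np.unique(below, return_counts=True)
        ad_vals = np.array(
            [ey_obs_sum - float(self.expected_potential(v, cause)[treated].sum())
             for v in values]
        )
        return float(np.average(ad_vals, weights=counts))

    def _check_z_star(self, z_star: float) -> None:
        if not 0 < z_star <= float(self.z.max()):
            raise ValueError(
                f"z_star must lie in (0, max Z]; got {z_star:g} "
                f"with max Z = {self.z.max():.3g}"
            )


def true_estimands(
    truth: SyntheticTruth, z_grid, z_star: float, cause: str = "natural"
) -> dict:
    """Evaluate the true aDRF on a grid and the true AD/DAD at a threshold."""
    curve = np.array([truth.mu(z, cause) for z in np.asarray(z_grid, dtype=float)])
    return {
        "mu": curve,
        "AD": truth.ad(z_star, cause),
        "DAD": truth.dad(z_star, cause),
    }


def generate(config: GeneratorConfig | None = None) -> tuple[StudyTimeSeries, SyntheticTruth]:
    """Generate a synthetic study and its ground truth.

    All randomness derives from ``config.seed``; identical configs give
    bitwise-identical series.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    # winter(+1)/summer(-1) wave shared by exposure, humidity and mortality
    phase = 2.0 * np.pi * (doy - cfg.temp_phase_day) / 365.25
    winter_wave = np.cos(phase)

    noise = rng.normal(0.0, cfg.temp_sd, cfg.n_days)
    if cfg.temp_ar > 0:
        for i in range(1, cfg.n_days):
            noise[i] = cfg.temp_ar * noise[i - 1] + np.sqrt(
                1 - cfg.temp_ar**2
            ) * noise[i]
    temp = cfg.temp_mean - cfg.temp_amplitude * winter_wave + noise

    humidity = np.clip(
        cfg.humidity_mean
        + cfg.humidity_amplitude * winter_wave
        + rng.normal(0.0, cfg.humidity_sd, cfg.n_days),
        20.0,
        100.0,
    )

    month = dates.month.to_numpy()
    day = dates.day.to_numpy()
    holiday = np.zeros(cfg.n_days, dtype=int)
    for m, d in _HOLIDAYS:
        holiday[(month == m) & (day == d)] = 1
    influenza = (doy <= 45).astype(int)  # mid-winter epidemic window
    weekend = np.asarray(dates.dayofweek >= 5, dtype=int)

    # lag 0-1 exposure, drawn directly at the analysis level
    log_mean = (
        cfg.alpha0
        + cfg.seasonal_coef * winter_wave
        + cfg.temp_coef * (temp - cfg.temp_mean)
        + cfg.weekend_coef * weekend
    )
    eps = rng.normal(0.0, 1.0, cfg.n_days)
    if cfg.exposure_tail_cut > 0:
        # rejection sampling keeps the residual law smooth (no boundary atom)
        out = np.abs(eps) > cfg.exposure_tail_cut
        while out.any():
            eps[out] = rng.normal(0.0, 1.0, int(out.sum()))
            out = np.abs(eps) > cfg.exposure_tail_cut
    z = np.exp(log_mean + cfg.sigma_z * eps)

    # per-cause outcome baseline (everything except the dose-response term)
    season_mort = (
        cfg.winter_mort_coef * winter_wave
        + cfg.temp_mort_quad * (temp - cfg.temp_mort_ref) ** 2
    )
    g_obs = _dose_response(z, cfg)
    effect_scale = 1.0 + cfg.interaction * (temp - cfg.temp_mean)
    eta0 = {}
    counts = {}
    for cause, target in cfg.baseline_mean.items():
        # intercept chosen so the realized mean of E[Y] hits the target
        unnorm = season_mort + g_obs * effect_scale
        b0 = np.log(target) - np.log(np.mean(np.exp(unnorm)))
        eta0_full = b0 + season_mort
        lam = np.exp(eta0_full + g_obs * effect_scale)
        if cfg.overdispersion > 0:
            frailty = rng.gamma(
                1.0 / cfg.overdispersion, cfg.overdispersion, cfg.n_days
            )
            counts[cause] = rng.poisson(lam * frailty)
        else:
            counts[cause] = rng.poisson(lam)
        eta0[cause] = eta0_full

    frame = pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "pm10": z,
            "temp": temp,
            "humidity": humidity,
            "holiday": holiday,
            "influenza": influenza,
            "deaths_natural": counts["natural"],
            "deaths_cvd": counts["cvd"],
            "deaths_resp": counts["resp"],
        }
    )
    series = StudyTimeSeries.from_frame(frame, exposure_precomputed=True)

    keep = slice(MAX_LAG, None)
    truth = SyntheticTruth(
        config=cfg,
        z=z[keep].copy(),
        temp=temp[keep].copy(),
        eta0={c: v[keep].copy() for c, v in eta0.items()},
        winter_wave=winter_wave[keep].copy(),
        weekend=weekend[keep].astype(float).copy(),
    )
    return series, truth
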