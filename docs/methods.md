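# Methods

This note documents the statistical model behind `gpsdrf`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the method's known limitations.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`.

## Model and identification

The unit is the day. The exposure `Z_i` is the lag 0-1 moving average of
the daily pollutant concentration — averaging today and yesterday makes
the no-interference assumption (a day's potential death count `Y_i(z)`
depends only on its own exposure) more defensible than using the same-day
level. Identification rests on unconfoundedness: exposure assignment is
independent of the potential outcomes given the measured covariates
(seasonality, temperature, humidity, calendar indicators). This is
untestable; the covariate set follows the standard confounder battery of
daily air-pollution mortality analyses.

The generalized propensity score is the conditional density of exposure
given covariates. With the log-normal exposure model

    log Z_i ~ N(alpha_0 + alpha_X' X_i, sigma_Z),

the GPS is evaluated *on the log scale*: `r(z; x)` is the normal density
of `log z` at the fitted conditional mean, without the `1/z`
change-of-variables factor that would make it a density of `Z` itself.
Any strictly monotone per-exposure-level transformation of the GPS
preserves the balancing property and the conditioning it induces, so this
choice affects the numeric GPS values but not the method; it is fixed for
reproducibility.

Exposure-model design (per analysable day): six day-of-week dummies
(Monday reference), holiday and influenza indicators, a piecewise-linear
calendar spline with 5 df per year and equally spaced knots, a cubic
spline of temperature at lag 0-3 with 5 df and interior knots at equally
spaced quantiles, humidity and humidity squared, and a July–August
indicator (summer population dip). `sigma_Z` is the maximum-likelihood
estimate (residual sum of squares divided by `N`, not `N - p`); at
`N ≈ 1460` the difference is immaterial but the convention must be fixed.

The outcome model conditions on the exposure and the GPS only:

    Y_i(z) ~ quasi-Poisson(lambda_i),  log lambda_i = s(z, r(z; X_i)).

`s` is a low-rank bivariate thin-plate smoother: both coordinates are
min-max standardized to [0, 1] (exposure and GPS live on incommensurate
scales), `K` knots are chosen among the observed standardized pairs by a
deterministic greedy max-min space-filling design (seeded at the point
nearest the centroid; no RNG, so fits are reproducible without a seed),
radial columns `phi(d) = d^2 log d` are evaluated at distances to the
knots, and the inter-knot kernel matrix is absorbed (eigendecomposition
with an absolute-eigenvalue floor of 1e-8, then post-multiplication by
`Omega^{-1/2}`) so the roughness penalty is exactly the identity on the
radial coefficients and zero on the unpenalized block `[1, z~, r~]`. The
smoother is isotropic on the standardized square; no tensor-product or
anisotropic variant is implemented.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` (`n_knots`) | 50 | radial knots of the outcome smoother; resolution of `s` |
| smoothing grid | 40 log-spaced points in [1e-6, 1e6] | GCV candidates, then one golden-section refinement of log-lambda around the grid minimizer (tolerance 0.05) |
| `GCV_GAMMA` | 1.0 | optional per-edf charge in the *selection* score (plain GCV by default) |
| z grid | 100 equally spaced points over the observed exposure range | aDRF evaluation |
| `M` (`mc_draws`) | 1000 | Monte-Carlo draws for DAD |
| `B` (`n_boot`) | 1000 | bootstrap replicates; 90% percentile CIs |
| thresholds | 20, 40, 50 μg/m³ | WHO annual guideline, EU annual limit, EU daily limit |

GCV uses the deviance form `n · deviance / (n − edf)^2` with `edf` the
trace of the penalized influence matrix at the final IRLS step. The
quasi-Poisson dispersion is the Pearson statistic over `n − edf`; it
rescales uncertainty only — penalized point estimates are identical to
Poisson maximum penalized likelihood.

Penalized IRLS details: log-link working weights, initialization at
`log(y + 0.5)`, convergence when the relative deviance change falls below
1e-8 (at most 100 iterations), linear predictor clipped to ±30 to guard
the exponential. Along the smoothing grid each fit warm-starts from the
previous one.

## Counterfactual prediction and its guard rails

Predicting `Y_i(z)` re-evaluates the GPS at the counterfactual `z` for
every day, then standardizes `(z, r̂)` by the *training* ranges and clamps
each coordinate into [0, 1]. Counterfactual GPS values can fall far
outside the observed cloud (a deep-winter day evaluated at a mid-summer
exposure has a tiny density); clamping bounds that extrapolation, and the
number of clamped evaluations is counted on the results object and logged.
Ties at balance-block quartile boundaries go to the lower block; degenerate
blocks (fewer than two days on either side) are dropped with the weights
renormalized, and the block-combined standard error assumes independent
blocks, `sqrt(sum w_j^2 se_j^2)` — the combination rule is not uniquely
determined by the procedure's description, so it is fixed and documented
here.

DAD uses the empirical counterfactual distribution: draws are taken
uniformly from the observed below-threshold exposures. Because that
support is finite, the package also provides the exact enumeration
(`exact_dad`), which the Monte-Carlo estimator approaches at the expected
`1/sqrt(M)` rate; the enumeration also defines the generator's true DAD.

The bootstrap resamples day-rows of the fully constructed analysis table
(lagged variables attached) i.i.d. with replacement and refits both models
per replicate, re-selecting the smoothing parameter by default; a
`freeze_lambda` option fixes it at the point estimate's choice, trading a
slightly narrower interval for an order-of-magnitude speedup (the
calibration study below uses it). Replicates that fail to fit are dropped
and counted; more than 5% failures abort. The i.i.d. scheme ignores serial
correlation in the mortality series — a deliberate simplification; block
or residual bootstraps are out of scope.

## The synthetic generator

`gpsdrf.synthetic.generate` emulates a four-year (1461-day) mid-latitude
urban study calibrated to the kind of setting the method targets:
sinusoidal temperature (mean 14.5 °C, amplitude 10, noise sd 3, peak in
late July), winter-peaking humidity, Italian-style holiday calendar, a
mid-winter influenza window, and a winter-peaking pollutant whose lag 0-1
exposure is log-normal given the shared seasonal wave, temperature,
and weekday, calibrated to a marginal mean ≈ 52, SD ≈ 32 and maximum
≈ 220–240 μg/m³ (the exposure residual is truncated at ±2.8 sigma —
drawn by rejection, so the law stays smooth — because an untruncated
lognormal at this coefficient of variation produces maxima far beyond
anything such a study records, and those stray maxima dominate the
standardized geometry of the outcome smoother). Death counts are Poisson
(an optional gamma-frailty multiplier exercises the quasi-likelihood
path) with means ≈ 28 (natural), 10.3 (cardiovascular), 2.5 (respiratory),
a mild winter mortality excess, a weak U-shaped temperature term, and the
saturating dose-response

    g(z) = gamma * log(1 + z / tau),   gamma = 0.13, tau = 20,

steep below ~50 μg/m³ and flattening above. `gamma` is set so that the
true `AD(40)` is about 2.7–2.9% of all natural-cause deaths over the four
years — the effect share a study of this design reports; `tau = 20` puts
the curvature in the low-concentration range. An optional
exposure-temperature interaction (`interaction`, default 0) multiplies
`g(z)` by `1 + delta (T_i − 14.5)`; the effect-modification analyses use
`delta = 0.05`, i.e. a hot-day relative effect about three times the
cold-day one, within the range reported for summer-vs-winter PM effects.

Two generator choices deserve emphasis.

**The exposure is drawn at the analysis level.** The generator draws the
lag 0-1 exposure itself i.i.d. log-normal given the same day's covariates
and stores it in the pollutant column (`exposure_precomputed=True` in the
data layer). Averaging independently drawn daily concentrations instead
would make the analysed exposure's log non-normal, serially correlated,
and attenuated relative to the generating coefficients — the generator
would no longer know its own truth. Drawing at the analysis level makes
the data satisfy the exposure model *exactly*, so parameter recovery,
residual normality and bootstrap calibration can be scored against exact
truth. The cost: the synthetic raw column is already the aggregated
exposure, so the 2-day-averaging code path is exercised by unit tests on
real-shaped CSVs rather than by the generator.

**Confounding strength is deliberately moderate at the defaults.** The
default seasonal loading on the exposure gives marginal
temperature-imbalance t statistics around 2–5 across exposure classes.
Our own large-sample experiments (reproducible with the generator) show
why: the GPS surface conditions on a *scalar*. At a fixed exposure `z`,
days whose conditional mean lies symmetrically above and below `log z`
share the same GPS value, so `E[Y | Z = z, R = r]` is a two-branch
mixture. The average dose-response function is still identified — the
averaging over days re-weights the mixture correctly — but treated-only
sums (`AD`, `DAD`) and stratified curves are only approximately
identified, with a bias that grows with the product of exposure
seasonality and baseline-mortality seasonality (at city-realistic
seasonal amplitudes, t ≈ 13, we measure an inherent `AD(40)`
overstatement of ~30% even with the *exact* conditional-mean surface, and
substantially more for the fitted low-rank smoother). The defaults
therefore sit where the scalar-GPS machinery is adequate; the balance and
effect-modification analyses, which need strong confounding to be
meaningful, use a dedicated strongly-confounded configuration
(`seasonal_coef=0.21, temp_coef=-0.014, sigma_z=0.52`). Passing tests at
the defaults shows the pipeline recovers truth where its assumptions
hold; it does not certify treated-day estimands under severe confounding
— see Limitations.

What the generator does **not** emulate: serial correlation in exposure,
temperature or mortality (everything is independent across days given the
seasonal structure — matching the bootstrap's assumption; an AR(1)
temperature option exists, off by default); measurement error in the
monitors; multi-station averaging; population change; day-of-week
structure in mortality.

## Numerical and degenerate-input conventions

- Dates must be strictly consecutive; gaps and duplicates are hard errors
  (lags would silently mix non-adjacent days). Days with incomplete lag
  windows (the first three) are dropped, never imputed.
- Constant covariates, tied quantile knots, or rank-deficient exposure
  designs raise named errors (the collinear columns are identified by
  pivoted QR).
- Zero-variance groups in balance checks return an infinite-t sentinel
  rather than raising, so one degenerate covariate does not abort a table.
- The exposure-class edges (0–20, 20–40, 40–70, 70+) are right-open.
- `AD` at a threshold above the observed maximum returns 0 with a warning
  (an estimand of an empty set, not an error); `DAD` there is undefined
  and raises.

## Problem sizes used in validation

The recovery studies fit 20 independent four-year studies (N = 1458
analysable days, K = 50) for the curve and `AD(40)` checks; the bootstrap
calibration study uses 200 replicate studies of 500 days with B = 200 and
the smoothing parameter frozen per study at its GCV choice; DAD
Monte-Carlo convergence is checked at M up to 10,000 against exact
enumeration. A single study's `AD(40)` estimate carries ≈ 13% relative
standard deviation from Poisson noise alone (the observed counts enter
the estimator), so single-seed impact numbers are reported alongside
multi-study averages.

## Limitations

- **Scalar-GPS bias for treated-only estimands.** As described above,
  `AD`/`DAD` and temperature-stratified curves inherit a systematic
  component under strong confounding that conditioning on the scalar GPS
  cannot remove. Users analysing heavily seasonal pollutants should read
  stratified curves descriptively and compare `AD` against a
  covariate-adjusted regression benchmark.
- **Wiggliness at sparse exposure ranges.** With few low-exposure days
  the curve can develop local wiggles tied to knot placement; `K` and the
  smoothing grid are exposed, but adaptive smoothing is not implemented.
- **GCV instability.** Near-flat GCV profiles can flip the selected
  smoothing between very smooth and flexible fits on replicate data;
  `GCV_GAMMA > 1` (e.g. 1.4) is available to push selection toward
  smoother fits.
- **No positivity trimming.** All days are retained by design (the point
  of the impact estimands is the whole study period); strong positivity
  violations surface as clamped counterfactual evaluations, which are
  counted and should be inspected.
- The i.i.d. bootstrap understates uncertainty if mortality is serially
  correlated beyond the modelled seasonality.
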