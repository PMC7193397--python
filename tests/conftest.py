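"""Shared fixtures: synthetic studies and fitted models.

Session-scoped fixtures keep the expensive fits (exposure + penalized
outcome model on ~1500 days) shared across test modules.
"""

import numpy as np
import pytest

from gpsdrf import ExposureModel, GPSDoseResponse
from gpsdrf.synthetic import GeneratorConfig, generate

#: Strongly confounded configuration used by the balance and
#: effect-modification checks: season and temperature drive both the
#: exposure and the outcome hard enough that marginal imbalance t
#: statistics reach the 5-15 range.
STRONG_CONFOUNDING = dict(seasonal_coef=0.21, temp_coef=-0.014, sigma_z=0.52)


@pytest.fixture(scope="session")
def default_study():
    """Default four-year synthetic study with its ground truth."""
    return generate(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def default_series(default_study):
    return default_study[0]


@pytest.fixture(scope="session")
def default_truth(default_study):
    return default_study[1]


@pytest.fixture(scope="session")
def gps_results(default_series):
    """Fitted log-normal exposure model on the default study."""
    return ExposureModel.from_series(default_series).fit()


@pytest.fixture(scope="session")
def fitted_natural(default_series):
    """Full GPS dose-response fit for natural-cause deaths."""
    return GPSDoseResponse(default_series, cause="natural").fit()


@pytest.fixture(scope="session")
def confounded_study():
    """Strongly confounded study for balance diagnostics."""
    return generate(GeneratorConfig(seed=7, **STRONG_CONFOUNDING))


@pytest.fixture(scope="session")
def confounded_gps(confounded_study):
    series, _ = confounded_study
    return ExposureModel.from_series(series).fit(), series


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
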