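import warnings

import numpy as np
import pytest

from bpsurv import ModelSpec, SamplerConfig, fit, simulate_survival

# short-but-converging sampler settings for unit tests
QUICK = SamplerConfig(chains=4, tune=300, draws=300, thin=2, seed=7)


@pytest.fixture(scope="session")
def quick_cfg() -> SamplerConfig:
    return QUICK


@pytest.fixture(scope="session")
def exp_cohort():
    """Simulated exponential cohort with ~30% administrative censoring."""
    data, truth = simulate_survival(
        300,
        [np.log(0.5), 0.8],
        censoring={"mode": "administrative", "target_frac": 0.3},
        seed=11,
    )
    return data, truth


@pytest.fixture(scope="session")
def exp_posterior(exp_cohort):
    data, _ = exp_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(ModelSpec("exponential", "linear"), data, sampler_config=QUICK)


@pytest.fixture(scope="session")
def wb_posterior(exp_cohort):
    data, _ = exp_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(ModelSpec("weibull", "linear"), data, sampler_config=QUICK)
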