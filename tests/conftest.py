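import numpy as np
import pytest

import ahmbench as ab


@pytest.fixture
def tiny_abundance():
    """Three-year history with known one-step differences (1.2, 0.9)."""
    return ab.AbundanceSeries(np.array([2000, 2001, 2002]), np.array([5.0, 6.2, 7.1]))


@pytest.fixture
def default_params():
    return ab.default_params()


@pytest.fixture(scope="session")
def sarw_bundle():
    """A 50-year noise-bearing simulation under the SaRw generator."""
    spec = ab.ScenarioSpec(generator="SaRw", n_years=50, start_year=1970,
                           obs_cv=0.0, seed=1234)
    return ab.simulate_population(spec)


@pytest.fixture(scope="session")
def sarw_table(sarw_bundle):
    """One-step-ahead forecasts of all six models on the SaRw simulation."""
    b = sarw_bundle
    models = list(ab.AHM_MODEL_IDS) + ["persistence", "wetland"]
    return ab.run_one_step_ahead(b.observed, b.wetlands, b.harvest, models, (1975, 2019))
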