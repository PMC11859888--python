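import numpy as np
import pytest

from fertigation import synthetic, trial_data


@pytest.fixture(scope="session")
def reference_design():
    """The published 4 x 3 split-plot dose grid with unfertilized checks."""
    return synthetic.make_design(emulate_reference=True, n_reps=3)


@pytest.fixture(scope="session")
def yield_means():
    return trial_data.load_yield_means()


@pytest.fixture(scope="session")
def quality_means():
    return trial_data.load_quality_means()


@pytest.fixture(scope="session")
def surface_summary():
    return trial_data.load_surface_summary()


@pytest.fixture
def noiseless_truth():
    return synthetic.SyntheticTruth(sigma_mainplot=0.0, sigma_subplot=0.0,
                                    sigma_mainplot_brix=0.0,
                                    sigma_subplot_brix=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)
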