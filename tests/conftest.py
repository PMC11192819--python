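import numpy as np
import pytest

from memval.design import build_design
from memval.hierarchical import HierarchicalEvaluationModel, McmcConfig
from memval.task import default_generator_params, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def presented_dataset():
    """A strong-signal experiment generated by the presented-items model."""
    return generate_dataset(33, default_generator_params("presented"), seed=101)


@pytest.fixture(scope="session")
def presented_design(presented_dataset):
    return build_design(presented_dataset)


@pytest.fixture(scope="session")
def presented_fits(presented_design):
    """All three comparison models fitted to the presented-generated data at
    reduced sampler settings (shared across comparison tests)."""
    fits = {}
    for i, model in enumerate(("recalled", "presented", "td")):
        fits[model] = HierarchicalEvaluationModel(
            model, mcmc=McmcConfig.desk(seed=500 + i)
        ).fit(presented_design)
    return fits
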