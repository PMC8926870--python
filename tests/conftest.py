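import warnings

import numpy as np
import pytest

from asfintake.harmonize import energy_adjust_table
from asfintake.intake_model import IntakeModel, ModelConfig
from asfintake.synthetic import (SurveyDesign, WorldConfig,
                                 generate_true_intakes, simulate_population,
                                 simulate_surveys)

# arviz emits a refactor FutureWarning on import; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

FOOD = "unprocessed_red_meat"


@pytest.fixture(scope="session")
def small_world():
    """Scaled-down world: 3 regions x 4 countries, 6 age bands, one food."""
    config = WorldConfig(foods=(FOOD,), seed=3)
    return generate_true_intakes(config)


@pytest.fixture(scope="session")
def small_surveys(small_world):
    design = SurveyDesign.default(small_world, surveys_per_country=2, seed=3)
    surveys = simulate_surveys(small_world, design, seed=3)
    return energy_adjust_table(surveys)


@pytest.fixture(scope="session")
def small_population(small_world):
    return simulate_population(small_world.config)


@pytest.fixture(scope="session")
def fitted_model(small_surveys):
    """One shared hierarchical-model fit on the scaled-down world."""
    config = ModelConfig(n_draws=500, n_chains=2, warmup=250, seed=11)
    return IntakeModel(config=config).fit(small_surveys)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
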