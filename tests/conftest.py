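import numpy as np
import pytest

from diabscreen import (
    ScenarioConfig,
    apply_exclusions,
    classify_frame,
    fit_risk_models,
    generate_model_survey,
    generate_projection_survey,
    predict_risk,
)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(population_size=6000, seed=11).validate()


@pytest.fixture(scope="session")
def model_survey(small_config):
    return generate_model_survey(small_config)


@pytest.fixture(scope="session")
def classified_survey(model_survey):
    kept, _, _ = apply_exclusions(model_survey)
    return classify_frame(kept)


@pytest.fixture(scope="session")
def fitted_model(classified_survey):
    return fit_risk_models(classified_survey)


@pytest.fixture(scope="session")
def projection_survey(small_config):
    frame = generate_projection_survey(small_config)
    kept, _, _ = apply_exclusions(frame)
    return kept


@pytest.fixture(scope="session")
def profiles(projection_survey, fitted_model):
    return predict_risk(projection_survey, fitted_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
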