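import warnings

import pytest

from isodiet.synthetic_data import SimScenario, make_sources


@pytest.fixture(scope="session")
def scenario():
    return SimScenario(seed=1)


@pytest.fixture(scope="session")
def sources(scenario):
    return make_sources(scenario)


@pytest.fixture(scope="session")
def spec1(sources):
    from isodiet.diet_model import build_model_spec

    return build_model_spec("model1", sources)


@pytest.fixture(scope="session")
def spec2(sources):
    from isodiet.diet_model import build_model_spec

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return build_model_spec("model2", sources)


@pytest.fixture(autouse=True)
def _quiet_glycolytic_fallback():
    # meat/fish carry no carbohydrate, so whole-diet specs warn about the
    # Ala glycolytic fallback on every build; keep test output readable
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*glycolytic.*",
                                category=UserWarning)
        yield
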