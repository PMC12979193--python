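import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def global_params():
    from fishflow import GLOBAL_PARAMS

    return GLOBAL_PARAMS


@pytest.fixture
def nutrient_table():
    from fishflow import default_nutrient_table

    return default_nutrient_table()
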