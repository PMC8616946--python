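import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_conditions():
    from sodscreen import Conditions

    return Conditions()


@pytest.fixture(scope="session")
def small_table():
    """A small deterministic synthetic materials table."""
    from sodscreen import FixtureSpec, generate_materials_table

    return generate_materials_table(FixtureSpec(n_materials=40, seed=7))
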