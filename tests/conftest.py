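import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        deadline=None,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wish():
    from dietscore import builtin_index

    return builtin_index("WISH")


@pytest.fixture(scope="session")
def wish2():
    from dietscore import builtin_index

    return builtin_index("WISH2.0")


@pytest.fixture(scope="session")
def eat():
    from dietscore import builtin_index

    return builtin_index("EAT-Lancet")


@pytest.fixture(scope="session")
def table1():
    from dietscore import table1_fixture

    return table1_fixture()
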