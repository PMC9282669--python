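import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schema():
    from ecoachkb import default_schema

    return default_schema()


@pytest.fixture(scope="session")
def rulebase():
    from ecoachkb import default_rulebase

    return default_rulebase()


@pytest.fixture(scope="session")
def canonical_sessions():
    from ecoachkb import all_canonical

    return all_canonical(seed=7)


@pytest.fixture()
def case1_session():
    from ecoachkb import canonical_case

    return canonical_case(1, seed=7)


@pytest.fixture()
def case1_graph(case1_session):
    from ecoachkb import session_graph

    return session_graph(case1_session)
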