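import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    from lesionlab import LesionConfig

    return LesionConfig()


@pytest.fixture(scope="session")
def paper_table():
    from lesionlab import paper_lambda_table

    return paper_lambda_table()


@pytest.fixture(scope="session")
def paper_summary(paper_table):
    from lesionlab import reproduce_paper_summary

    return reproduce_paper_summary(paper_table)
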