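import pytest

from ssc_audit import (
    PathwayConfig,
    build_australia_cohort,
    build_japan_cohort,
    run_pathway,
    tabulate,
)


@pytest.fixture(scope="session")
def japan_records():
    return build_japan_cohort()


@pytest.fixture(scope="session")
def australia_records():
    return build_australia_cohort()


@pytest.fixture(scope="session")
def japan_results(japan_records):
    return [run_pathway(r) for r in japan_records]


@pytest.fixture(scope="session")
def australia_results(australia_records):
    return [run_pathway(r, robson_mode="paper_compat") for r in australia_records]


@pytest.fixture(scope="session")
def japan_report(japan_results):
    return tabulate(japan_results)


@pytest.fixture
def config():
    return PathwayConfig()
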