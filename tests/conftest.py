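import pytest

from gcsfcea import datasets, load_scenario


def _load(scenario_id: str):
    return load_scenario(datasets.fixture_path(scenario_id))


@pytest.fixture(scope="session")
def all_fixtures():
    """All 18 bundled calibrated scenarios, keyed by id."""
    return {sid: _load(sid) for sid in datasets.fixture_ids()}


@pytest.fixture(scope="session")
def bc_austria(all_fixtures):
    return all_fixtures["austria_bc_filgrastim"]


@pytest.fixture(scope="session")
def nsclc_france(all_fixtures):
    return all_fixtures["france_nsclc_filgrastim"]
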