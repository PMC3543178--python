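import pytest

from careforce import OccupationGroup, load_baseline, project, published_baseline_table


@pytest.fixture()
def baseline():
    return load_baseline()


@pytest.fixture(scope="session")
def published_streams():
    return published_baseline_table()


@pytest.fixture(scope="session")
def calibration_run(published_streams):
    """Baseline run with demand and supply pinned to the published
    projection table, exercising only the downstream accounting."""
    params = load_baseline()
    demand = {g: s["demand"] for g, s in published_streams.items()}
    supply = {
        g: s["supply"] for g, s in published_streams.items() if "supply" in s
    }
    return project(params, demand_streams=demand, supply_streams=supply)


@pytest.fixture()
def rn():
    return OccupationGroup.RN


@pytest.fixture()
def lpn():
    return OccupationGroup.LPN


@pytest.fixture()
def hca():
    return OccupationGroup.HCA
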