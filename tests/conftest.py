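import pytest
from hypothesis import settings

import ocrvkit as k

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ontology():
    return k.build_ocrv()


@pytest.fixture(scope="session")
def small_config():
    # desk-scale fixture: full 20-county catchment, small tables
    return k.SourceConfig(
        n_patients=60, brfss_n_per_county=30, tracts_per_county=2,
        inconsistency_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return k.generate_all(small_config, seed=1)


@pytest.fixture(scope="session")
def small_source(small_data):
    return k.DataSourceDecl.from_dataframes(small_data.tables())


@pytest.fixture(scope="session")
def small_graph(small_source):
    return k.materialize(k.default_obda_model(), small_source)
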