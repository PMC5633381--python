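import pytest

from lohflux.markers import default_marker_map, starting_genotype


@pytest.fixture(scope="session")
def marker_map():
    return default_marker_map()


@pytest.fixture(scope="session")
def g0(marker_map):
    return starting_genotype(marker_map)
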