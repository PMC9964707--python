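import pytest

from cwnirs import (
    ProbeGeometry,
    load_extinction_table,
)
from cwnirs.synthetic import default_reference, default_simulation_geometry


@pytest.fixture(scope="session")
def chrom():
    return load_extinction_table()


@pytest.fixture(scope="session")
def geom():
    """Analysis geometry: 8 mm separation, DPF table at 740/840 nm only."""
    return ProbeGeometry()


@pytest.fixture(scope="session")
def sim_geom():
    """Simulation geometry: DPF extended over the full instrument range."""
    return default_simulation_geometry()


@pytest.fixture(scope="session")
def ref():
    return default_reference()
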