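import numpy as np
import pytest

from bindscape.geometry import GeoPosition
from bindscape.synth import (
    SimulationSpec,
    make_fixture_protein,
    simulate,
    two_well_potential,
)


@pytest.fixture(scope="session")
def two_well():
    return two_well_potential()


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(seed=7, steps=6000, n_copies=4)


@pytest.fixture(scope="session")
def small_run(two_well, small_spec):
    """A short two-well run shared by unit tests (ground truth in .truth)."""
    return simulate(two_well, small_spec)


@pytest.fixture(scope="session")
def fixture_protein(tmp_path_factory, small_spec):
    """(pdb_path, ground-truth frame, sidecar) of the synthetic protein."""
    d = tmp_path_factory.mktemp("fixture")
    pdb = d / "fixture.pdb"
    sidecar = d / "frame.json"
    _, frame, meta = make_fixture_protein(small_spec, pdb_path=pdb,
                                          sidecar_path=sidecar)
    return pdb, frame, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_geo(rng):
    def _make(n):
        lat = np.degrees(np.arcsin(rng.uniform(-1, 1, n)))
        lon = rng.uniform(-180, 180, n)
        return [GeoPosition(lat=a, lon=o) for a, o in zip(lat, lon)]

    return _make
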