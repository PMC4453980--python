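import numpy as np
import pytest
from hypothesis import settings

import shelxfrag as sf

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def db():
    return sf.load_builtin_db()


@pytest.fixture(scope="session")
def ccf3(db):
    return sf.lookup(db, "OC(CF3)3")


@pytest.fixture()
def default_fixture(db):
    text, truth = sf.build_fixture(sf.FixtureSpec(), db)
    return text, truth


def random_cell(rng: np.random.Generator) -> sf.UnitCell:
    """A random valid (possibly strongly triclinic) unit cell."""
    while True:
        a, b, c = rng.uniform(4.0, 30.0, size=3)
        al, be, ga = rng.uniform(60.0, 120.0, size=3)
        try:
            return sf.UnitCell(a, b, c, al, be, ga)
        except sf.ShelxFragError:
            continue


MINIMAL_WATER_DB = """\
<water>
RESI H2O
DFIX 0.9584 O1 H1 O1 H2
FRAG 17 1 1 1 90 90 90
O1 -8 0 0 0
H1 -1 0.09 0.03 0
H2 -1 -0.03 0.09 0
</water>
"""
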