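import numpy as np
import pytest

import saftgmie as sg
from saftgmie.fixtures import toy_associating_binary, toy_nonassociating_binary


@pytest.fixture(scope="session")
def library():
    return sg.default_library()


@pytest.fixture(scope="session")
def gbl_eos(library):
    """Pure oxolan-2-one (γ-butyrolactone) model."""
    return sg.GammaMieEoS(library, ["oxolan-2-one"])


@pytest.fixture(scope="session")
def gbl_water_eos(library):
    """Associating binary: oxolan-2-one + water."""
    return sg.GammaMieEoS(library, ["oxolan-2-one", "water"])


@pytest.fixture(scope="session")
def toy_binary():
    return toy_nonassociating_binary()


@pytest.fixture(scope="session")
def toy_assoc():
    return toy_associating_binary()


@pytest.fixture(scope="session")
def ideal_gas_eos():
    """Single segment with ε = 0 and no sites: an exactly ideal gas."""
    from saftgmie.groups import GroupLibrary, MieGroup

    lib = GroupLibrary([MieGroup("X", 1, 1.0, 4.0, 12.0, 6.0, 0.0, {}, 10.0)], [], [])
    lib.build_molecule("xmol", {"X": 1})
    return sg.GammaMieEoS(lib, ["xmol"])


@pytest.fixture(scope="session")
def lj_eos():
    """Single 12-6 segment (Lennard-Jones limit), ε/kB = 100 K, σ = 3 Å."""
    from saftgmie.groups import GroupLibrary, MieGroup

    lib = GroupLibrary([MieGroup("LJ", 1, 1.0, 3.0, 12.0, 6.0, 100.0, {}, 10.0)], [], [])
    lib.build_molecule("lj", {"LJ": 1})
    return sg.GammaMieEoS(lib, ["lj"])
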