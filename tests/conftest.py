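import numpy as np
import pytest

from thvforge import assembly as asm
from thvforge import config as cfgmod
from thvforge import softgoods, stent


@pytest.fixture(scope="session")
def thv_a():
    return cfgmod.thv_a()


@pytest.fixture(scope="session")
def thv_b():
    return cfgmod.thv_b()


@pytest.fixture(scope="session")
def stent_curve_a(thv_a):
    return stent.build_stent_curve(thv_a.profile, thv_a.support)


@pytest.fixture(scope="session")
def stent_curve_b(thv_b):
    return stent.build_stent_curve(thv_b.profile, thv_b.support)


@pytest.fixture(scope="session")
def assembly_a(thv_a):
    return asm.assemble_valve(thv_a)


@pytest.fixture(scope="session")
def assembly_b(thv_b):
    return asm.assemble_valve(thv_b)


@pytest.fixture(scope="session")
def leaflet_a(thv_a):
    return softgoods.build_leaflet(thv_a)


@pytest.fixture(scope="session")
def leaflet_b(thv_b):
    return softgoods.build_leaflet(thv_b)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
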