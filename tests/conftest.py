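import pytest

from zonpbpk.compounds import builtin_cocktail
from zonpbpk.physiology import build_default_physiology


@pytest.fixture(scope="session")
def phys():
    return build_default_physiology()


@pytest.fixture(scope="session")
def cocktail(phys):
    return {m.name: m for m in builtin_cocktail(phys)}


@pytest.fixture(scope="session")
def caffeine_family(cocktail):
    return [cocktail["caffeine"], cocktail["paraxanthine"]]


@pytest.fixture(scope="session")
def torsemide_family(cocktail):
    return [cocktail["torsemide"], cocktail["hydroxytorsemide"]]
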