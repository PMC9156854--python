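import pytest

from craydeb import load_species

SPECIES = (
    "austropotamobius_torrentium",
    "astacus_astacus",
    "pacifastacus_leniusculus",
    "procambarus_virginalis",
)


@pytest.fixture(scope="session")
def aa():
    return load_species("astacus_astacus")


@pytest.fixture(scope="session")
def at():
    return load_species("austropotamobius_torrentium")


@pytest.fixture(scope="session")
def pl():
    return load_species("pacifastacus_leniusculus")


@pytest.fixture(scope="session")
def pv():
    """Marbled crayfish: smallest egg and fastest embryo, so the cheapest
    species for integration-heavy oracle tests."""
    return load_species("procambarus_virginalis")


@pytest.fixture(scope="session")
def all_female(aa, at, pl, pv):
    return {p.species: p for p in (aa, at, pl, pv)}
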