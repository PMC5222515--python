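import pytest

from herbnetpharm import (
    BipartiteNetwork,
    CompoundRecord,
    load_disease_targets,
    load_herb_compounds,
    load_herb_literature,
)


@pytest.fixture(scope="session")
def compounds150():
    return load_herb_compounds()


@pytest.fixture(scope="session")
def herbs20():
    return load_herb_literature()


@pytest.fixture(scope="session")
def targets33():
    return load_disease_targets()


@pytest.fixture(scope="session")
def radix_salviae_rows(compounds150):
    return [c for c in compounds150 if c.herb_id == "radix_salviae"]


@pytest.fixture
def toy_ct_network():
    """3 compounds from 2 herbs, 3 edges; c3 declared but isolated."""
    net = BipartiteNetwork(
        left_kind="compound",
        right_kind="target",
        left_nodes={"c1", "c2"},
        right_nodes={"t1", "t2"},
        edges={("c1", "t1"), ("c2", "t1"), ("c2", "t2")},
        node_meta={"c1": {"herb_id": "A"}, "c2": {"herb_id": "A"}},
        relation="targets",
    )
    net.validate()
    return net


def make_compound(cid="c1", herb="h1", ob=50.0, dl=0.5, **kw):
    return CompoundRecord(
        compound_id=cid, name=cid, herb_id=herb, ob=ob, dl=dl, **kw
    )


@pytest.fixture
def compound_factory():
    return make_compound
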