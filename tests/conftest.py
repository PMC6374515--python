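import pytest

from semaplex import classify_record, default_species_tree, load_fixture

#: the worked example subtree: two basal singletons plus a five-copy
#: within-species sponge clade under one polytomy
TOY_TREE = (
    "((Aquee_Plexin1,Mleid_Plexin1,"
    "(Aquee_PlexinA1,Aquee_PlexinA2,Aquee_PlexinA3,Aquee_PlexinA4,Aquee_PlexinA5)));"
)


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def fixture_records():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_classifications(fixture_records):
    return {(r.species, r.protein_id): classify_record(r) for r in fixture_records}


@pytest.fixture()
def toy_newick():
    return TOY_TREE
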