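from __future__ import annotations

import pytest

from phenesim import fixtures, infer, similarity


@pytest.fixture(scope="session")
def mini_ont():
    return fixtures.load_mini_ontology()


@pytest.fixture(scope="session")
def mini_ont_bridged():
    return fixtures.load_mini_ontology(with_bridges=True)


@pytest.fixture(scope="session")
def fixture_config():
    return fixtures.fixtures_validation_config()


@pytest.fixture(scope="session")
def corngrass():
    return fixtures.load_corngrass()


@pytest.fixture(scope="session")
def mac1():
    return fixtures.load_mac1()


@pytest.fixture(scope="session")
def anthocyanin_matrix():
    ont = fixtures.load_anthocyanin_ontology()
    ds = fixtures.load_anthocyanin()
    profiles = infer.infer_dataset(ds, ont)
    return similarity.all_pairs(profiles)
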