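import logging
import random

import pytest

import ontoview as ov

logging.getLogger("ontoview").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def kidney():
    return ov.builtin_fixture("kidney")


@pytest.fixture(scope="session")
def cornea():
    return ov.builtin_fixture("cornea")


@pytest.fixture(scope="session")
def midbrain_hindbrain():
    return ov.builtin_fixture("midbrain_hindbrain")


@pytest.fixture(scope="session")
def neural_crest():
    return ov.builtin_fixture("neural_crest")


@pytest.fixture(scope="session")
def part_relation_hierarchy():
    return ov.builtin_fixture("part_relation_hierarchy")


@pytest.fixture(scope="session")
def kidney_closure(kidney):
    return ov.materialize(kidney.fragment)


@pytest.fixture(scope="session")
def cornea_closure(cornea):
    return ov.materialize(cornea.fragment)


@pytest.fixture(scope="session")
def profiles():
    return ov.default_profiles()


PART_OF = ov.Curie.parse("BFO:0000050")
OVERLAPS = ov.Curie.parse("RO:0002131")


def random_spec(seed: int, max_terms: int = 15, max_props: int = 3,
                allow_chains: bool = True) -> ov.RandomOntologySpec:
    """One draw from the family of random-ontology conditions used throughout
    the suite: up to `max_terms` terms, up to `max_props` properties, random
    subproperty/transitivity/chain axioms, fully determined by `seed`."""
    rng = random.Random(seed * 2 + 1)
    return ov.RandomOntologySpec(
        n_terms=rng.randint(0, max_terms),
        n_properties=rng.randint(1, max_props),
        p_subclass=rng.uniform(0.0, 0.4),
        p_relation=rng.uniform(0.0, 0.4),
        subproperty_depth=rng.randint(0, 2),
        enable_transitive=True,
        enable_chains=allow_chains and bool(seed % 2),
        seed=seed,
    )


def curie(text: str) -> ov.Curie:
    return ov.Curie.parse(text)
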