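import numpy as np
import pytest

from pirdap import PirnaRecord, RunConfig
from pirdap.io import DiseaseOntology
from pirdap.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_records():
    return [
        PirnaRecord("p1", "ATTGCATTGCATTGCATTGCATTG"),
        PirnaRecord("p2", "GGGGCCCCAAAATTTTGGGGCCCC"),
        PirnaRecord("p3", "ATTGCATTGCATTGCATTGCATAC"),
        PirnaRecord("p4", "TTTTTTTTTTTTAAAAAAAAAAAA"),
    ]


@pytest.fixture
def chain_ontology():
    # d -> a -> r
    return DiseaseOntology.from_edges([("d", "a"), ("a", "r")])


@pytest.fixture
def sibling_ontology():
    # two diseases under one shared root
    return DiseaseOntology.from_edges([("d1", "r"), ("d2", "r")])


@pytest.fixture
def fast_config():
    """Cheap config for unit tests; defaults are exercised in acceptance."""
    return RunConfig(epochs=25, rf_estimators=30, bag_estimators=15,
                     two_step_estimators=15, n_bags=4, bag_rounds=2,
                     word_dim=16, n_filters=16, embed_dim=32, gcn_dim=16,
                     w2v_epochs=2)


@pytest.fixture(scope="session")
def small_study():
    """A small planted dataset shared by read-only tests."""
    spec = SyntheticSpec(m=30, n=8, density=0.1, seed=7)
    dataset, ontology, truth = generate(spec)
    return dataset, ontology, truth
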