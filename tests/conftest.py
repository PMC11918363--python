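import numpy as np
import pytest

from kgfuse.entity_tagger import Lexicon
from kgfuse.ontology import OntologyClass, OntologyGraph


def make_graph(spec: dict[str, tuple[str, list[str], str, list[str]]],
               ) -> OntologyGraph:
    """Build an OntologyGraph from {id: (label, synonyms, definition,
    parents)}."""
    classes = {cid: OntologyClass(id=cid, label=lab, synonyms=list(syn),
                                  definition=d, parents=list(par))
               for cid, (lab, syn, d, par) in spec.items()}
    return OntologyGraph(classes)


@pytest.fixture
def toy_graph() -> OntologyGraph:
    """Root R with branches X (child x1) and Y."""
    return make_graph({
        "R": ("root", [], "", []),
        "X": ("branch x", [], "", ["R"]),
        "Y": ("branch y", [], "", ["R"]),
        "x1": ("leaf", [], "", ["X"]),
    })


@pytest.fixture
def symptom_graph() -> OntologyGraph:
    """Small symptom ontology with the classes of the worked example."""
    return make_graph({
        "S:0": ("symptom root", [], "", []),
        "S:1": ("Drowsiness", ["drowsy", "sleepiness"],
                "reduced wakefulness", ["S:0"]),
        "S:2": ("Tiredness", ["tired"], "", ["S:0"]),
        "S:3": ("Pain", [], "", ["S:0"]),
        "S:4": ("pain relief", [], "", ["S:3"]),
    })


@pytest.fixture
def fig_sentence() -> list[str]:
    return "Very drowsy and tired and no pain relief at all .".split()


@pytest.fixture
def symptom_lexicon() -> Lexicon:
    """Toy symptom lexicon: drowsy/tired/pain only (single-token entries)."""
    return Lexicon(entries={"drowsy": "S:1", "tired": "S:2", "pain": "S:3"},
                   source="symptom", max_len=1,
                   node_source={"S:1": "symptom", "S:2": "symptom",
                                "S:3": "symptom"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
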