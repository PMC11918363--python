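"""Ontology parsing, graph combination, and top-level labelling."""

import numpy as np
import pytest

from conftest import make_graph
from kgfuse.ontology import (AmbiguousRootError, CollisionError,
                             OntologyGraph, assign_top_level_labels,
                             combine_graphs, load_ontology)
from kgfuse.synthetic_data import OntologySpec, generate_ontology

OBO_SMALL = """format-version: 1.4

[Term]
id: T:A
name: alpha

[Term]
id: T:B
name: beta
synonym: "second letter" EXACT []
def: "the beta class" [x:1]
is_a: T:A

[Term]
id: T:C
name: gamma
is_a: T:A

[Term]
id: T:D
name: obsolete delta
is_obsolete: true
is_a: T:A
"""

OWL_SMALL = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:oio="http://www.geneontology.org/formats/oboInOwl#">
  <owl:Class rdf:about="http://x.org/A">
    <rdfs:label>alpha</rdfs:label>
  </owl:Class>
  <owl:Class rdf:about="http://x.org/B">
    <rdfs:label>beta</rdfs:label>
    <oio:hasExactSynonym>second letter</oio:hasExactSynonym>
    <rdfs:subClassOf rdf:resource="http://x.org/A"/>
  </owl:Class>
  <owl:Class rdf:about="http://x.org/C">
    <rdfs:label>gamma</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://x.org/A"/>
  </owl:Class>
</rdf:RDF>
"""


def test_obo_load_nodes_edges_and_annotations(tmp_path):
    path = tmp_path / "small.obo"
    path.write_text(OBO_SMALL)
    g = load_ontology(path, "obo")
    assert g.n_nodes == 3 and g.n_edges == 2 and g.root == "T:A"
    cls = g.cls("T:B")
    assert cls.label == "beta"
    assert cls.synonyms == ["second letter"]
    assert cls.definition == "the beta class"
    assert "T:D" not in g.graph  # obsolete classes are dropped


def test_obo_single_class(tmp_path):
    path = tmp_path / "one.obo"
    path.write_text("format-version: 1.4\n\n[Term]\nid: T:A\nname: only\n")
    g = load_ontology(path, "obo")
    assert g.n_nodes == 1 and g.n_edges == 0 and g.root == "T:A"


def test_owl_load(tmp_path):
    path = tmp_path / "small.owl"
    path.write_text(OWL_SMALL)
    g = load_ontology(path, "owl")
    assert g.n_nodes == 3 and g.n_edges == 2
    assert g.root == "http://x.org/A"
    assert g.cls("http://x.org/B").synonyms == ["second letter"]


def test_unparsable_file_is_a_format_error(tmp_path):
    path = tmp_path / "junk.owl"
    path.write_text("this is not RDF/XML")
    with pytest.raises(Exception, match="cannot parse"):
        load_ontology(path, "owl")


def test_multiple_roots_require_virtual_root(tmp_path):
    obo = ("format-version: 1.4\n\n[Term]\nid: T:A\nname: a\n\n"
           "[Term]\nid: T:B\nname: b\n\n"
           "[Term]\nid: T:C\nname: c\nis_a: T:A\n")
    path = tmp_path / "forest.obo"
    path.write_text(obo)
    with pytest.raises(AmbiguousRootError):
        load_ontology(path, "obo")
    g = load_ontology(path, "obo", virtual_root="VROOT")
    assert g.root == "VROOT" and g.n_nodes == 4 and g.n_edges == 3


@pytest.mark.parametrize("n_classes,n_top", [(860, 14), (37, 5), (2, 1)])
def test_generated_tree_has_n_minus_one_edges(n_classes, n_top):
    g = generate_ontology(OntologySpec(n_classes=n_classes, n_top=n_top,
                                       seed=7))
    assert g.n_nodes == n_classes
    assert g.n_edges == n_classes - 1


def test_combine_counts_union_plus_bridge():
    g1 = generate_ontology(OntologySpec(n_classes=3, n_top=2, seed=1,
                                        prefix="A"))
    g2 = generate_ontology(OntologySpec(n_classes=4, n_top=2, seed=2,
                                        prefix="B"))
    combined = combine_graphs(g1, g2)
    assert combined.n_nodes == 7 and combined.n_edges == 6
    assert combined.root == g1.root
    # bridging edge: g2's old root is now a child of g1's root
    assert g2.root in combined.children(g1.root)


def test_combine_two_single_node_graphs():
    a = make_graph({"A": ("a", [], "", [])})
    b = make_graph({"B": ("b", [], "", [])})
    c = combine_graphs(a, b)
    assert c.n_nodes == 2 and c.n_edges == 1


def test_combine_rejects_id_collision():
    a = make_graph({"A": ("a", [], "", [])})
    with pytest.raises(CollisionError):
        combine_graphs(a, make_graph({"A": ("a2", [], "", [])}))


def test_top_level_labels_toy(toy_graph):
    lab = assign_top_level_labels(toy_graph)
    assert lab.n_classes == 2
    assert lab.labels == {"X": 0, "x1": 0, "Y": 1}


def test_top_level_labels_chain():
    g = make_graph({"R": ("r", [], "", []), "a": ("a", [], "", ["R"]),
                    "b": ("b", [], "", ["a"]), "c": ("c", [], "", ["b"])})
    lab = assign_top_level_labels(g)
    assert lab.n_classes == 1
    assert set(lab.labels.values()) == {0}


def test_combined_label_space_adds_branch_counts():
    g1 = generate_ontology(OntologySpec(n_classes=60, n_top=14, seed=3,
                                        prefix="S"))
    g2 = generate_ontology(OntologySpec(n_classes=60, n_top=14, seed=4,
                                        prefix="D"))
    lab = assign_top_level_labels(combine_graphs(g1, g2))
    # g2's root becomes an extra child of g1's root: 14 + 14 branches
    assert lab.n_classes == 28


def test_label_counts_partition_non_root_nodes():
    g = generate_ontology(OntologySpec(n_classes=100, n_top=6, seed=9))
    lab = assign_top_level_labels(g)
    assert sorted(set(lab.labels.values())) == list(range(lab.n_classes))
    assert len(lab.labels) == g.n_nodes - 1


def test_labeling_invariant_to_insertion_order():
    spec = {"R": ("r", [], "", []), "X": ("x", [], "", ["R"]),
            "Y": ("y", [], "", ["R"]), "x1": ("", [], "", ["X"]),
            "y1": ("", [], "", ["Y"])}
    lab1 = assign_top_level_labels(make_graph(dict(spec)))
    lab2 = assign_top_level_labels(make_graph(dict(reversed(spec.items()))))
    assert lab1.labels == lab2.labels and lab1.n_classes == lab2.n_classes


def test_multi_parent_dag_uses_lexicographically_first_parent():
    g = make_graph({"R": ("r", [], "", []), "A": ("a", [], "", ["R"]),
                    "B": ("b", [], "", ["R"]),
                    "m": ("m", [], "", ["A", "B"])})
    lab = assign_top_level_labels(g)
    assert lab.labels["m"] == lab.labels["A"]


def test_edge_list_round_trip(tmp_path):
    g = generate_ontology(OntologySpec(n_classes=40, n_top=4, seed=5))
    g.save(tmp_path / "g")
    g2 = OntologyGraph.load(tmp_path / "g")
    assert g2.edges() == g.edges()
    assert g2.root == g.root
    for n in g.nodes():
        a, b = g.cls(n), g2.cls(n)
        assert (a.label, a.synonyms, a.definition) == \
               (b.label, b.synonyms, b.definition)
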