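"""Ontology-to-graph conversion and top-level node labelling.

Drug and symptom ontologies (OWL RDF/XML or OBO flat files) are reduced to
directed class graphs: one node per named class, one child-to-parent edge
per asserted subclass axiom, all other logical axioms ignored.  Two such
graphs can be combined into a single knowledge graph by bridging their
roots, and every node can be labelled with the top-level branch (child of
the root) it descends from — the supervision signal for the graph attention
network.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "OntologyClass", "OntologyGraph", "TopLevelLabeling",
    "load_ontology", "combine_graphs", "assign_top_level_labels",
    "AmbiguousRootError", "FormatError", "CollisionError", "ConnectivityError",
]

# OWL annotation properties commonly carrying synonyms / definitions;
# configurable because ontologies differ in which they use.
DEFAULT_SYNONYM_PROPERTIES = (
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym",
    "http://www.w3.org/2004/02/skos/core#altLabel",
)
DEFAULT_DEFINITION_PROPERTIES = (
    "http://purl.obolibrary.org/obo/IAO_0000115",
    "http://www.w3.org/2004/02/skos/core#definition",
)


class FormatError(ValueError):
    """The ontology file could not be parsed in the stated format."""


class AmbiguousRootError(ValueError):
    """More than one parentless class and no virtual root configured."""


class CollisionError(ValueError):
    """Node identifier sets of two graphs being combined are not disjoint."""


class ConnectivityError(ValueError):
    """A node is unreachable from the root."""


@dataclass
class OntologyClass:
    """A named ontology class with the annotations used as node text."""

    id: str
    label: str = ""
    synonyms: list[str] = field(default_factory=list)
    definition: str = ""
    parents: list[str] = field(default_factory=list)


@dataclass
class TopLevelLabeling:
    """Node -> top-level-branch class index; the root is unlabelled."""

    labels: dict[str, int]
    n_classes: int


class OntologyGraph:
    """Directed class graph: edges run child -> parent, single root.

    Wraps a :class:`networkx.DiGraph`; node attribute ``cls`` holds the
    :class:`OntologyClass` record.
    """

    def __init__(self, classes: dict[str, OntologyClass],
                 virtual_root: str | None = None,
                 bridged_roots: list[str] | None = None):
        self.bridged_roots = list(bridged_roots or [])
        g = nx.DiGraph()
        for cid, cls in classes.items():
            g.add_node(cid, cls=cls)
        for cid, cls in classes.items():
            for parent in cls.parents:
                if parent not in classes:
                    raise FormatError(
                        f"class {cid!r} references unknown parent {parent!r}")
                g.add_edge(cid, parent)
        roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
        if len(roots) == 0 and g.number_of_nodes() > 0:
            raise FormatError("no parentless class found (cycle at top level?)")
        if len(roots) > 1:
            if virtual_root is None:
                raise AmbiguousRootError(
                    f"{len(roots)} parentless classes ({roots[:5]}...); "
                    "enable a virtual root to adopt them")
            vr = OntologyClass(id=virtual_root, label=virtual_root)
            g.add_node(virtual_root, cls=vr)
            for r in roots:
                g.add_edge(r, virtual_root)
                g.nodes[r]["cls"].parents.append(virtual_root)
            roots = [virtual_root]
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("subclass relation contains a cycle")
        if g.number_of_nodes() > 1 and not nx.is_weakly_connected(g):
            raise ConnectivityError("class graph is not weakly connected")
        self.graph = g
        self.root = roots[0] if roots else None

    # ------------------------------------------------------------ accessors
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def cls(self, node_id: str) -> OntologyClass:
        return self.graph.nodes[node_id]["cls"]

    def parents(self, node_id: str) -> list[str]:
        return sorted(self.graph.successors(node_id))

    def children(self, node_id: str) -> list[str]:
        return sorted(self.graph.predecessors(node_id))

    # ------------------------------------------------------------------- io
    def save(self, out_dir: str | Path) -> None:
        """Write a plain-text edge list (child TAB parent) plus a JSON
        node-attribute sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "edges.tsv", "w") as fh:
            for child, parent in self.edges():
                fh.write(f"{child}\t{parent}\n")
        attrs = {
            nid: {"label": c.label, "synonyms": c.synonyms,
                  "definition": c.definition}
            for nid, c in ((n, self.cls(n)) for n in self.nodes())
        }
        with open(out / "nodes.json", "w") as fh:
            json.dump({"root": self.root, "bridged_roots": self.bridged_roots,
                       "nodes": attrs}, fh, indent=1)

    @classmethod
    def load(cls, in_dir: str | Path) -> "OntologyGraph":
        src = Path(in_dir)
        with open(src / "nodes.json") as fh:
            meta = json.load(fh)
        classes = {
            nid: OntologyClass(id=nid, label=a["label"],
                               synonyms=list(a["synonyms"]),
                               definition=a["definition"])
            for nid, a in meta["nodes"].items()
        }
        with open(src / "edges.tsv") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                child, parent = line.split("\t")
                classes[child].parents.append(parent)
        return cls(classes, bridged_roots=meta.get("bridged_roots"))


# ---------------------------------------------------------------- OBO input

_OBO_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _obo_quoted(value: str) -> str:
    m = _OBO_QUOTED.search(value)
    return m.group(1).replace('\\"', '"') if m else value.strip()


def _load_obo(path: Path, virtual_root: str | None) -> OntologyGraph:
    import obonet

    try:
        raw = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    classes: dict[str, OntologyClass] = {}
    for nid, data in raw.nodes(data=True):
        synonyms = [_obo_quoted(s) for s in data.get("synonym", [])]
        classes[nid] = OntologyClass(
            id=nid,
            label=data.get("name", ""),
            synonyms=synonyms,
            definition=_obo_quoted(data.get("def", "")),
            parents=sorted(data.get("is_a", [])),
        )
    # keep only parents that survived obsolete filtering
    for cls in classes.values():
        cls.parents = [p for p in cls.parents if p in classes]
    return OntologyGraph(classes, virtual_root=virtual_root)


# ---------------------------------------------------------------- OWL input

def _load_owl(path: Path, virtual_root: str | None,
              synonym_properties=DEFAULT_SYNONYM_PROPERTIES,
              definition_properties=DEFAULT_DEFINITION_PROPERTIES,
              ) -> OntologyGraph:
    import rdflib
    from rdflib.namespace import OWL, RDF, RDFS

    g = rdflib.Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse OWL (RDF/XML) file {path}: {exc}") from exc

    named = {s for s in g.subjects(RDF.type, OWL.Class)
             if isinstance(s, rdflib.URIRef)}
    deprecated = {
        s for s in named
        if any(str(o).lower() == "true" for o in g.objects(s, OWL.deprecated))
    }
    named -= deprecated
    syn_props = [rdflib.URIRef(p) for p in synonym_properties]
    def_props = [rdflib.URIRef(p) for p in definition_properties]

    classes: dict[str, OntologyClass] = {}
    for s in named:
        sid = str(s)
        labels = [str(o) for o in g.objects(s, RDFS.label)]
        synonyms = sorted(str(o) for p in syn_props for o in g.objects(s, p))
        definition = ""
        for p in def_props:
            vals = [str(o) for o in g.objects(s, p)]
            if vals:
                definition = vals[0]
                break
        parents = sorted(
            str(o) for o in g.objects(s, RDFS.subClassOf)
            if isinstance(o, rdflib.URIRef) and str(o) in
            {str(n) for n in named}
        )
        classes[sid] = OntologyClass(id=sid, label=labels[0] if labels else "",
                                     synonyms=synonyms, definition=definition,
                                     parents=parents)
    return OntologyGraph(classes, virtual_root=virtual_root)


def load_ontology(path: str | Path, format: str,
                  virtual_root: str | None = None) -> OntologyGraph:
    """Parse an ontology file into a directed class graph.

    Parameters
    ----------
    path : file path to an OWL (RDF/XML) or OBO 1.4 file.
    format : ``"owl"`` or ``"obo"``.
    virtual_root : optional identifier; when the ontology has several
        parentless classes, a virtual root with this id adopts them all.
        Disabled (``None``) by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "obo":
        return _load_obo(path, virtual_root)
    if format == "owl":
        return _load_owl(path, virtual_root)
    raise ValueError(f"unknown ontology format {format!r}")


# ------------------------------------------------------------- combination

def combine_graphs(g1: OntologyGraph, g2: OntologyGraph) -> OntologyGraph:
    """Union two class graphs, bridging ``g2``'s root under ``g1``'s root.

    The node set is the union of both node sets and the edge set is the
    union of both edge sets plus exactly one edge making ``g2``'s root a
    child of ``g1``'s root, so |V| = |V1|+|V2| and |E| = |E1|+|E2|+1.
    """
    overlap = set(g1.graph.nodes) & set(g2.graph.nodes)
    if overlap:
        raise CollisionError(f"node identifiers shared by both graphs: "
                             f"{sorted(overlap)[:5]}")
    classes: dict[str, OntologyClass] = {}
    for g in (g1, g2):
        for nid in g.graph.nodes:
            c = g.cls(nid)
            classes[nid] = OntologyClass(id=c.id, label=c.label,
                                         synonyms=list(c.synonyms),
                                         definition=c.definition,
                                         parents=list(c.parents))
    classes[g2.root].parents.append(g1.root)
    bridged = g1.bridged_roots + g2.bridged_roots + [g2.root]
    return OntologyGraph(classes, bridged_roots=bridged)


# ----------------------------------------------------------- top-level map

def assign_top_level_labels(g: OntologyGraph) -> TopLevelLabeling:
    """Label each non-root node by its top-level-branch ancestor.

    The label classes are the root's children in sorted-identifier order;
    in a combined knowledge graph a bridged sub-ontology root is not itself
    a class but expands into its own children, so combining two ontologies
    with 14 branches each yields 28 classes.  On a node with several
    parents the lexicographically smallest parent is followed
    (deterministic tie-break).  The root itself is excluded; a bridged root
    node is assigned the branch of its first child.
    """
    bridged = set(g.bridged_roots)
    branches: list[str] = []
    frontier = g.children(g.root)
    while frontier:
        node = frontier.pop(0)
        if node in bridged:
            frontier = g.children(node) + frontier
        else:
            branches.append(node)
    branches = sorted(branches)
    index = {b: i for i, b in enumerate(branches)}
    labels: dict[str, int] = {}

    def branch_of(node: str) -> int:
        path = []
        while node not in labels and node not in index:
            if node in bridged:  # adopt the branch of the first child
                path.append(node)
                node = g.children(node)[0]
                continue
            path.append(node)
            parents = g.parents(node)
            if not parents:
                raise ConnectivityError(f"node {node!r} unreachable from root")
            node = parents[0]
        lab = labels[node] if node in labels else index[node]
        labels[node] = lab
        for n in path:
            labels[n] = lab
        return lab

    for node in g.nodes():
        if node != g.root:
            branch_of(node)
    return TopLevelLabeling(labels=labels, n_classes=len(branches))
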