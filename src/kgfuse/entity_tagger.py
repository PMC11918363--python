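"""Rule-based lexicon tagging of drug and symptom mentions.

A lexicon maps normalized surface forms (labels, synonyms, brand names of
knowledge-graph classes) to node identifiers.  Tagging is greedy
left-to-right longest match over token n-grams, case-insensitive, within a
sentence; no stemming or lemmatization is applied, to avoid false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = ["Lexicon", "TaggedSpan", "TaggedSequence", "build_lexicon", "tag",
           "normalize_surface"]

_STRIP = ".,;:!?()[]{}'\"`"


def normalize_surface(surface: str) -> str:
    """Lowercase, strip surrounding punctuation, collapse whitespace."""
    words = [w.strip(_STRIP) for w in surface.lower().split()]
    return " ".join(w for w in words if w)


@dataclass
class Lexicon:
    """Normalized surface form -> knowledge-graph node identifier."""

    entries: dict[str, str]
    source: str = "combined"          # drug | symptom | combined
    max_len: int = 1                  # longest entry, in tokens
    node_source: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for surface in sorted(self.entries):
                nid = self.entries[surface]
                fh.write(f"{surface}\t{nid}\t"
                         f"{self.node_source.get(nid, self.source)}\n")

    @classmethod
    def load(cls, path: str | Path, source: str = "combined") -> "Lexicon":
        entries: dict[str, str] = {}
        node_source: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                surface, nid, src = line.split("\t")
                entries[surface] = nid
                node_source[nid] = src
        max_len = max((len(s.split()) for s in entries), default=1)
        return cls(entries=entries, source=source, max_len=max_len,
                   node_source=node_source)


@dataclass(frozen=True)
class TaggedSpan:
    """A matched entity: inclusive token range plus its graph node."""

    start: int
    end: int
    node: str
    source: str = "combined"


@dataclass
class TaggedSequence:
    tokens: list[str]
    spans: list[TaggedSpan]

    def __post_init__(self):
        last_end = -1
        for sp in self.spans:
            if not (0 <= sp.start <= sp.end < len(self.tokens)):
                raise ValueError(f"span {sp} outside sentence")
            if sp.start <= last_end:
                raise ValueError("spans overlap or are unsorted")
            last_end = sp.end


def _node_depths(g: OntologyGraph) -> dict[str, int]:
    depths = nx.shortest_path_length(g.graph.reverse(copy=False), g.root)
    return dict(depths)


def build_lexicon(g: OntologyGraph, source: str = "combined",
                  node_source: dict[str, str] | None = None) -> Lexicon:
    """Collect all class labels and synonyms into a lookup lexicon.

    When two classes share a normalized surface form the shallower node
    (closer to the root, i.e. the more general class) wins; remaining ties
    go to the lexicographically smaller identifier.  Classes with no usable
    annotation contribute their normalized identifier.
    """
    if g.n_nodes == 0:
        logger.warning("building lexicon from an empty ontology")
        return Lexicon(entries={}, source=source)
    depths = _node_depths(g)
    entries: dict[str, str] = {}
    for nid in g.nodes():
        if nid == g.root:
            continue  # the root is an organizational node, not a mention
        cls = g.cls(nid)
        surfaces = [cls.label] + list(cls.synonyms)
        surfaces = [normalize_surface(s) for s in surfaces if s]
        if not surfaces:
            surfaces = [normalize_surface(nid)]
        for surface in surfaces:
            if not surface:
                continue
            if surface in entries:
                incumbent = entries[surface]
                keep = min((depths.get(incumbent, 1 << 30), incumbent),
                           (depths.get(nid, 1 << 30), nid))[1]
                if keep != incumbent:
                    entries[surface] = keep
                logger.info("lexicon collision on %r: %s vs %s -> %s",
                            surface, incumbent, nid, entries[surface])
            else:
                entries[surface] = nid
    max_len = max((len(s.split()) for s in entries), default=1)
    ns = dict(node_source) if node_source else {n: source for n in g.nodes()}
    return Lexicon(entries=entries, source=source, max_len=max_len,
                   node_source=ns)


def merge_lexicons(drug: Lexicon, symptom: Lexicon) -> Lexicon:
    """Combined drug+symptom lexicon; on a shared surface, drug wins."""
    entries = dict(symptom.entries)
    entries.update(drug.entries)
    node_source = {**{n: "symptom" for n in symptom.entries.values()},
                   **{n: "drug" for n in drug.entries.values()},
                   **symptom.node_source, **drug.node_source}
    max_len = max(drug.max_len, symptom.max_len)
    return Lexicon(entries=entries, source="combined", max_len=max_len,
                   node_source=node_source)


def tag(tokens: list[str], lex: Lexicon) -> TaggedSequence:
    """Greedy left-to-right longest-match tagging over token n-grams.

    At each position the longest matching n-gram (up to the lexicon's
    ``max_len``) is taken; matched tokens are consumed, so spans never
    overlap.  Matching is case-insensitive on normalized surfaces.
    """
    if not tokens:
        raise ValueError("cannot tag an empty token list")
    norm = [normalize_surface(t) for t in tokens]
    spans: list[TaggedSpan] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(lex.max_len, len(tokens) - i), 0, -1):
            window = [w for w in norm[i:i + n]]
            surface = " ".join(w for w in window if w)
            if surface and surface in lex.entries:
                nid = lex.entries[surface]
                spans.append(TaggedSpan(
                    start=i, end=i + n - 1, node=nid,
                    source=lex.node_source.get(nid, lex.source)))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return TaggedSequence(tokens=list(tokens), spans=spans)
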