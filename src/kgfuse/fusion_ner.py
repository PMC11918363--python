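"""Knowledge fusion of ontology node embeddings with transformer states.

The *graph concat* model: a rule-based tagger marks drug/symptom mentions in
the input sentence, each tagged word's node embedding is injected at its
pivotal (first) wordpiece — every other position, including remaining
wordpieces, untagged words, special tokens and padding, carries zeros — and
the resulting aligned knowledge vector ``v~`` is concatenated with the
transformer representation ``T`` into ``T~ = [T ; v~]``, which feeds a
three-neuron linear IOB head.

Three fusion variants are provided:

- ``fixed``: the GNN is a frozen lookup table (no gradient into the graph),
- ``adaptive``: the GAT weights train jointly with the encoder and head,
- ``adaptive_subgraph``: instead of the node embedding, the k-hop
  neighborhood subgraph of the tagged entity is run through the GAT and
  pooled (concatenated global max and average pooling), giving a 2*d_G-wide
  knowledge block.

A model constructed without a knowledge source is the knowledge-free
baseline with an identical encoder and head geometry minus the knowledge
block.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._tensor import Tensor, concatenate
from .encoder import EncodedInput, TinyTransformerEncoder, WordPieceTokenizer
from .entity_tagger import Lexicon, TaggedSequence, tag
from .graph_embedder import (GATNetwork, NodeEmbeddingTable, NodeFeatureTable,
                             message_passing_edges)
from .nn import Linear, Module
from .ontology import OntologyGraph

__all__ = ["VariantConfig", "KnowledgeVector", "FusedRepresentation",
           "align_knowledge", "fuse", "subgraph_pool", "FusionNERModel",
           "N_IOB_CLASSES"]

N_IOB_CLASSES = 3  # O / B / I head width

VARIANTS = ("fixed", "adaptive", "adaptive_subgraph")


@dataclass
class VariantConfig:
    """Fusion variant selector; ``k`` (hop radius) only applies to the
    subgraph variant (default 2)."""

    variant: str = "fixed"
    k: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "adaptive_subgraph":
            if self.k is None:
                self.k = 2
            if self.k <= 0:
                raise ValueError("hop radius k must be positive")
        elif self.k is not None:
            raise ValueError("k is only defined for the subgraph variant")


@dataclass
class KnowledgeVector:
    """Wordpiece-aligned knowledge block ``v~`` (zeros off-pivot)."""

    v_aligned: np.ndarray  # (L, d_G)


@dataclass
class FusedRepresentation:
    T: np.ndarray          # (L, d_T)
    T_tilde: np.ndarray    # (L, d_T + d_G)


def pivot_positions(ts: TaggedSequence, enc: EncodedInput,
                    ) -> list[tuple[int, str]]:
    """(wordpiece position, node id) for the pivotal piece of every word
    inside a tagged span."""
    out = []
    for span in ts.spans:
        for w in range(span.start, span.end + 1):
            if w >= len(enc.word_to_pieces):
                raise ValueError("encoded input does not cover all words")
            lo, hi = enc.word_to_pieces[w]
            if hi > lo:  # words truncated away have empty ranges
                out.append((lo, span.node))
    return out


def align_knowledge(ts: TaggedSequence, emb: NodeEmbeddingTable,
                    enc: EncodedInput) -> KnowledgeVector:
    """Place each tagged word's node embedding at its pivotal wordpiece.

    A word split into n pieces receives the embedding at its first piece
    followed by n-1 zero rows; untagged words, special tokens and padding
    are all-zero rows.
    """
    L = len(enc.piece_ids)
    v = np.zeros((L, emb.dim))
    for pos, node in pivot_positions(ts, enc):
        v[pos] = emb.vector(node)  # KeyError naming the node if missing
    return KnowledgeVector(v_aligned=v)


def fuse(T: np.ndarray, v: KnowledgeVector) -> FusedRepresentation:
    """Per-position concatenation ``T~ = [T ; v~]`` (no position mixing)."""
    if T.shape[0] != v.v_aligned.shape[0]:
        raise ValueError(f"sequence length mismatch: T has {T.shape[0]} "
                         f"positions, v~ has {v.v_aligned.shape[0]}")
    return FusedRepresentation(T=T, T_tilde=np.concatenate([T, v.v_aligned],
                                                           axis=-1))


def khop_subgraph(g: OntologyGraph, node: str, k: int,
                  ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Nodes and local (src, dst) message-passing arrays of the k-hop
    neighborhood of ``node``, ignoring edge direction."""
    if node not in g.graph:
        raise KeyError(f"node {node!r} not in graph")
    und = g.graph.to_undirected(as_view=True)
    members = sorted(nx.ego_graph(und, node, radius=k).nodes)
    local = {n: i for i, n in enumerate(members)}
    pairs = {(local[c], local[p]) for c, p in g.edges()
             if c in local and p in local}
    pairs |= {(b, a) for a, b in pairs}
    pairs |= {(i, i) for i in range(len(members))}
    arr = np.array(sorted(pairs), dtype=np.int64)
    return members, arr[:, 0], arr[:, 1]


def subgraph_pool(g: OntologyGraph, node: str, cfg: VariantConfig,
                  gat: GATNetwork, feats: NodeFeatureTable,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Run the GAT on the k-hop subgraph of ``node`` and pool its node
    representations: concatenated element-wise max and mean (2*d_G)."""
    if cfg.variant != "adaptive_subgraph":
        raise ValueError("subgraph pooling requires the subgraph variant")
    members, src, dst = khop_subgraph(g, node, cfg.k)
    rows = [feats.node_ids.index(m) for m in members]
    h = Tensor(feats.matrix).gather(np.array(rows))
    z = gat.embed(h, src, dst, len(members), rng)   # (M, d_G)
    return concatenate([z.max(axis=0), z.mean(axis=0)], axis=-1)


class FusionNERModel(Module):
    """Transformer + aligned knowledge block + 3-class IOB head.

    Construct with ``graph=None`` (and no embedding table) for the
    knowledge-free baseline.  With ``cfg.variant == "fixed"`` the embedding
    table is a frozen lookup and no gradient reaches any GNN parameter;
    the adaptive variants own a :class:`GATNetwork` whose weights train
    with the rest of the model.
    """

    def __init__(self, encoder: TinyTransformerEncoder,
                 tokenizer: WordPieceTokenizer,
                 lexicon: Lexicon | None = None,
                 cfg: VariantConfig | None = None,
                 embedding_table: NodeEmbeddingTable | None = None,
                 graph: OntologyGraph | None = None,
                 gat: GATNetwork | None = None,
                 feats: NodeFeatureTable | None = None,
                 head_dropout: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.lexicon = lexicon
        self.cfg = cfg
        self.head_dropout = head_dropout
        self.is_baseline = lexicon is None
        if self.is_baseline:
            self.d_g = 0
        elif cfg is None:
            raise ValueError("a knowledge-equipped model needs a VariantConfig")
        elif cfg.variant == "fixed":
            if embedding_table is None:
                raise ValueError("fixed variant needs a NodeEmbeddingTable")
            self._table = embedding_table     # plain data: never trained
            self.d_g = embedding_table.dim
        else:
            if gat is None or feats is None or graph is None:
                raise ValueError("adaptive variants need graph, GAT and "
                                 "node features")
            self.graph = graph
            self.gat = gat                     # Module: trains with the rest
            self._feats = feats
            self._node_index = {n: i for i, n in enumerate(feats.node_ids)}
            self._src, self._dst = message_passing_edges(graph,
                                                         self._node_index)
            d = gat.cfg.embedding_dim
            self.d_g = 2 * d if cfg.variant == "adaptive_subgraph" else d
        self.head = Linear(encoder.hidden_size + self.d_g, N_IOB_CLASSES, rng)

    # -------------------------------------------------------------- tagging
    def tag_words(self, words: list[str]) -> TaggedSequence:
        if self.is_baseline:
            return TaggedSequence(tokens=list(words), spans=[])
        return tag(words, self.lexicon)

    # -------------------------------------------------------------- forward
    def forward(self, encs: list[EncodedInput],
                tagged: list[TaggedSequence],
                rng: np.random.Generator | None = None) -> Tensor:
        """Batched logits of shape (batch, sequence length, 3)."""
        if len(encs) != len(tagged):
            raise ValueError("batch size mismatch between inputs and tags")
        L = max(len(e.piece_ids) for e in encs)
        B = len(encs)
        ids = np.zeros((B, L), dtype=np.int64)
        mask = np.zeros((B, L), dtype=np.int64)
        for i, e in enumerate(encs):
            ids[i, :len(e.piece_ids)] = e.piece_ids
            mask[i, :len(e.attention_mask)] = e.attention_mask
        T = self.encoder(ids, mask, rng)
        if self.is_baseline:
            fused = T
        else:
            v = self._knowledge_block(encs, tagged, B, L, rng)
            fused = concatenate([T, v], axis=-1)
        return self.head(fused.dropout(self.head_dropout, rng))

    __call__ = forward

    def _knowledge_block(self, encs, tagged, B: int, L: int,
                         rng: np.random.Generator | None) -> Tensor:
        variant = self.cfg.variant
        if variant == "fixed":
            v = np.zeros((B, L, self.d_g))
            for i, (e, ts) in enumerate(zip(encs, tagged)):
                v[i, :len(e.piece_ids)] = align_knowledge(
                    ts, self._table, e).v_aligned
            return Tensor(v)

        # adaptive variants: knowledge rows live inside the autodiff graph
        if variant == "adaptive":
            z = self.gat.embed(Tensor(self._feats.matrix), self._src,
                               self._dst, len(self._node_index), rng)
            row_of = self._node_index
            n_rows = len(self._node_index)
        else:  # adaptive_subgraph: one pooled row per distinct tagged node
            nodes = sorted({sp.node for ts in tagged for sp in ts.spans})
            pooled = [subgraph_pool(self.graph, n, self.cfg, self.gat,
                                    self._feats, rng).reshape(1, -1)
                      for n in nodes]
            row_of = {n: i for i, n in enumerate(nodes)}
            n_rows = len(nodes)
            z = (concatenate(pooled, axis=0) if pooled
                 else Tensor(np.zeros((0, self.d_g))))
        zero_row = Tensor(np.zeros((1, self.d_g)))
        z_ext = concatenate([z, zero_row], axis=0) if n_rows else zero_row
        idx = np.full((B, L), n_rows, dtype=np.int64)   # default: zero row
        for i, (e, ts) in enumerate(zip(encs, tagged)):
            for pos, node in pivot_positions(ts, e):
                if node not in row_of:
                    raise KeyError(f"node {node!r} missing from embeddings")
                idx[i, pos] = row_of[node]
        return z_ext.gather(idx.ravel()).reshape(B, L, self.d_g)

    # ------------------------------------------------------------- predict
    def predict_labels(self, encs: list[EncodedInput],
                       tagged: list[TaggedSequence],
                       n_words: list[int]) -> list[list[str]]:
        """Greedy per-word IOB labels read off each word's pivotal piece."""
        logits = self.forward(encs, tagged)  # eval mode: no dropout rng
        labels_out = []
        names = ("O", "B", "I")
        for i, e in enumerate(encs):
            labs = []
            for w in range(n_words[i]):
                lo, hi = e.word_to_pieces[w]
                labs.append(names[int(np.argmax(logits.data[i, lo]))]
                            if hi > lo else "O")
            labels_out.append(labs)
        return labels_out

    def gnn_parameter_checksum(self) -> float:
        """Sum of all GNN parameters (adaptive) or table entries (fixed);
        0.0 for the baseline.  Used to verify gradient isolation."""
        if self.is_baseline:
            return 0.0
        if self.cfg.variant == "fixed":
            return float(self._table.matrix.sum())
        return float(sum(p.data.sum() for p in self.gat.parameters()))
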