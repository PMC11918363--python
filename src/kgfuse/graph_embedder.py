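"""Node feature initialisation and graph-attention-network embeddings.

Each ontology class is rendered to a text string from its annotations
(label, synonyms, definition), embedded with a contextual text encoder to a
fixed-width feature vector, and a graph attention network (GAT) is then
trained on the class graph — either to predict each node's top-level branch
(node classification) or to score held-out subclass edges (link
prediction).  The last hidden GAT layer, before the task head, provides the
node-level embeddings consumed by the fusion NER model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from ._tensor import Tensor, masked_cross_entropy, segment_softmax, segment_sum
from .nn import AdamW, Linear, Module, glorot
from .ontology import OntologyGraph, TopLevelLabeling

logger = logging.getLogger(__name__)

__all__ = ["NodeFeatureTable", "GatConfig", "NodeEmbeddingTable",
           "assemble_node_text", "encode_node_features", "GATNetwork",
           "GATNodeEmbedder", "train_gat_node_classification",
           "train_gat_link_prediction", "DegenerateTaskError"]

SEPARATOR = " [SEP] "


class DegenerateTaskError(ValueError):
    """The supervised task has fewer than two classes."""


@dataclass
class NodeFeatureTable:
    """Initial node feature vectors (one per graph node, shared width)."""

    node_ids: list[str]
    matrix: np.ndarray  # (N, dim)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.node_ids):
            raise ValueError("feature matrix shape does not match node list")
        if not np.isfinite(self.matrix).all():
            raise ValueError("node features contain NaN/Inf")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        return self.matrix[self.node_ids.index(node_id)]


@dataclass
class GatConfig:
    """GAT hyperparameters; defaults sized for single-CPU experiments."""

    n_layers: int = 2
    n_heads: int = 4
    hidden_dim: int = 64
    embedding_dim: int = 128   # d_G: width of exported node embeddings
    dropout: float = 0.2
    epochs: int = 200
    learning_rate: float = 5e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_layers, self.n_heads, self.hidden_dim,
               self.embedding_dim, self.epochs) <= 0:
            raise ValueError("GAT sizes and epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class NodeEmbeddingTable:
    """Trained node embeddings: node -> vector of dimension d_G."""

    node_ids: list[str]
    matrix: np.ndarray
    provenance: str = "node_classification"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("embeddings contain NaN/Inf")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def vector(self, node_id: str) -> np.ndarray:
        if node_id not in self._index:
            raise KeyError(f"node {node_id!r} missing from embedding table")
        return self.matrix[self._index[node_id]]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "embeddings.tsv", "w") as fh:
            for nid, row in zip(self.node_ids, self.matrix):
                fh.write(nid + "\t" + ",".join(repr(float(x)) for x in row)
                         + "\n")
        with open(out / "embeddings.json", "w") as fh:
            json.dump({"dim": int(self.dim), "provenance": self.provenance,
                       **self.meta}, fh, indent=1)

    @classmethod
    def load(cls, in_dir: str | Path) -> "NodeEmbeddingTable":
        src = Path(in_dir)
        with open(src / "embeddings.json") as fh:
            meta = json.load(fh)
        node_ids, rows = [], []
        with open(src / "embeddings.tsv") as fh:
            for line in fh:
                nid, vals = line.rstrip("\n").split("\t")
                node_ids.append(nid)
                rows.append([float(x) for x in vals.split(",")])
        return cls(node_ids=node_ids, matrix=np.array(rows),
                   provenance=meta.pop("provenance"),
                   meta={k: v for k, v in meta.items() if k != "dim"})


# --------------------------------------------------------------- node text

def assemble_node_text(cls) -> str:
    """Concatenate a class's annotations: label, synonyms, definition.

    Segments are joined by a single separator token in fixed order; when
    every annotation is empty the class identifier is used instead.
    """
    segments = []
    if cls.label:
        segments.append(cls.label)
    segments.extend(s for s in cls.synonyms if s)
    if cls.definition:
        segments.append(cls.definition)
    return SEPARATOR.join(segments) if segments else cls.id


def encode_node_features(g: OntologyGraph, encoder, tokenizer,
                         ) -> NodeFeatureTable:
    """One feature vector per node: mean over final-layer wordpiece states
    of the assembled node text."""
    node_ids = g.nodes()
    texts = [assemble_node_text(g.cls(n)) for n in node_ids]
    matrix = encoder.encode_texts(texts, tokenizer)
    return NodeFeatureTable(node_ids=node_ids, matrix=matrix)


# ---------------------------------------------------------------- GAT core

class GATLayer(Module):
    """Single multi-head graph attention layer (additive attention).

    Per-edge scores e_ij = LeakyReLU(a_s . Wh_i + a_d . Wh_j) are normalised
    by softmax over each target node's in-neighborhood.
    """

    def __init__(self, d_in: int, d_out: int, n_heads: int,
                 rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_out = d_out
        self.W = Tensor(glorot(rng, d_in, n_heads * d_out), requires_grad=True)
        self.a_src = Tensor(glorot(rng, d_out, 1, (n_heads, d_out)),
                            requires_grad=True)
        self.a_dst = Tensor(glorot(rng, d_out, 1, (n_heads, d_out)),
                            requires_grad=True)

    def attention(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
                  n_nodes: int) -> tuple[Tensor, Tensor]:
        Wh = (h @ self.W).reshape(n_nodes, self.n_heads, self.d_out)
        alpha_s = (Wh * self.a_src).sum(axis=-1)   # (N, H)
        alpha_d = (Wh * self.a_dst).sum(axis=-1)
        e = (alpha_s.gather(src) + alpha_d.gather(dst)).leaky_relu(0.2)
        att = segment_softmax(e, dst, n_nodes)      # (E, H)
        return Wh, att

    def __call__(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
                 n_nodes: int, concat_heads: bool = True) -> Tensor:
        Wh, att = self.attention(h, src, dst, n_nodes)
        msg = Wh.gather(src) * att.reshape(len(src), self.n_heads, 1)
        out = segment_sum(msg, dst, n_nodes)        # (N, H, d_out)
        if concat_heads:
            return out.reshape(n_nodes, self.n_heads * self.d_out)
        return out.mean(axis=1)


class GATNetwork(Module):
    """Stacked GAT with an optional linear task head.

    ``embed`` returns the last hidden layer (width ``embedding_dim``), the
    exported node representation; ``forward`` adds the classification head.
    """

    def __init__(self, d_in: int, cfg: GatConfig, n_classes: int | None):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.layers = [
            GATLayer(d_in if i == 0 else cfg.hidden_dim * cfg.n_heads,
                     cfg.hidden_dim, cfg.n_heads, rng)
            for i in range(cfg.n_layers - 1)
        ]
        last_in = d_in if cfg.n_layers == 1 else cfg.hidden_dim * cfg.n_heads
        self.out_layer = GATLayer(last_in, cfg.embedding_dim, cfg.n_heads, rng)
        self.head = (Linear(cfg.embedding_dim, n_classes, rng)
                     if n_classes else None)

    def embed(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
              n_nodes: int, rng: np.random.Generator | None = None) -> Tensor:
        p = self.cfg.dropout
        for layer in self.layers:
            h = layer(h.dropout(p, rng), src, dst, n_nodes).elu()
        # final attention layer averages heads (standard GAT output layer)
        return self.out_layer(h.dropout(p, rng), src, dst, n_nodes,
                              concat_heads=False)

    def forward(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
                n_nodes: int, rng: np.random.Generator | None = None) -> Tensor:
        z = self.embed(h, src, dst, n_nodes, rng)
        if self.head is None:
            raise ValueError("network has no classification head")
        return self.head(z.elu())


def message_passing_edges(g: OntologyGraph, node_index: dict[str, int],
                          bidirectional: bool = True,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Edge arrays (src, dst) with self-loops; symmetrised by default.

    The class graph is directed child->parent; symmetrisation lets
    information also flow from ancestors to descendants, which a directed
    tree would otherwise starve.
    """
    pairs = {(node_index[c], node_index[p]) for c, p in g.edges()}
    if bidirectional:
        pairs |= {(b, a) for a, b in pairs}
    pairs |= {(i, i) for i in range(len(node_index))}  # self-loops
    arr = np.array(sorted(pairs), dtype=np.int64)
    return arr[:, 0], arr[:, 1]


# ------------------------------------------------------------- estimator

class GATNodeEmbedder(BaseEstimator):
    """Scikit-learn style estimator producing ontology node embeddings.

    Parameters mirror :class:`GatConfig`; ``task`` selects the supervised
    objective ("node_classification" needs a :class:`TopLevelLabeling`,
    "link_prediction" trains against held-out subclass edges).

    Attributes (after ``fit``)
    --------------------------
    embeddings_ : NodeEmbeddingTable
    report_ : dict with per-epoch losses and the held-out metric
    network_ : the trained :class:`GATNetwork`
    """

    def __init__(self, task: str = "node_classification", n_layers: int = 2,
                 n_heads: int = 4, hidden_dim: int = 64,
                 embedding_dim: int = 128, dropout: float = 0.2,
                 epochs: int = 200, learning_rate: float = 5e-3,
                 weight_decay: float = 0.0, bidirectional: bool = True,
                 val_fraction: float = 0.2, seed: int = 0):
        self.task = task
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden_dim = hidden_dim
        self.embedding_dim = embedding_dim
        self.dropout = dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.bidirectional = bidirectional
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _config(self) -> GatConfig:
        return GatConfig(n_layers=self.n_layers, n_heads=self.n_heads,
                         hidden_dim=self.hidden_dim,
                         embedding_dim=self.embedding_dim,
                         dropout=self.dropout, epochs=self.epochs,
                         learning_rate=self.learning_rate,
                         weight_decay=self.weight_decay, seed=self.seed)

    def fit(self, g: OntologyGraph, feats: NodeFeatureTable,
            labeling: TopLevelLabeling | None = None) -> "GATNodeEmbedder":
        cfg = self._config()
        node_ids = g.nodes()
        if feats.node_ids != node_ids:
            raise ValueError("feature table does not cover the graph's nodes")
        index = {n: i for i, n in enumerate(node_ids)}
        if self.task == "node_classification":
            if labeling is None:
                raise ValueError("node classification requires a labeling")
            missing = [n for n in node_ids
                       if n != g.root and n not in labeling.labels]
            if missing:
                raise ValueError(f"labeling misses nodes: {missing[:5]}")
            if labeling.n_classes < 2:
                raise DegenerateTaskError(
                    "node classification needs at least 2 top-level classes")
            self._fit_node_classification(g, feats, labeling, index, cfg)
        elif self.task == "link_prediction":
            if g.n_edges < 10:
                raise ValueError("link prediction needs at least 10 edges")
            self._fit_link_prediction(g, feats, index, cfg)
        else:
            raise ValueError(f"unknown task {self.task!r}")
        return self

    # ------------------------------------------------------------------
    def _export(self, net: GATNetwork, h: Tensor, src, dst, n_nodes,
                node_ids, provenance: str, report: dict) -> None:
        z = net.embed(h, src, dst, n_nodes)        # eval mode: rng=None
        self.network_ = net
        self.report_ = report
        self.embeddings_ = NodeEmbeddingTable(
            node_ids=list(node_ids), matrix=z.data.copy(),
            provenance=provenance,
            meta={"seed": self.seed, "config_hash": self._config().hash()})

    def _fit_node_classification(self, g, feats, labeling, index, cfg):
        node_ids = list(index)
        n = len(node_ids)
        src, dst = message_passing_edges(g, index, self.bidirectional)
        labels = np.zeros(n, dtype=np.int64)
        labelled = np.zeros(n, dtype=bool)
        for nid, lab in labeling.labels.items():
            labels[index[nid]] = lab
            labelled[index[nid]] = True

        rng = np.random.default_rng(cfg.seed)
        train_mask = np.zeros(n, dtype=bool)
        val_mask = np.zeros(n, dtype=bool)
        for lab in range(labeling.n_classes):   # stratified 80/20 node split
            members = np.flatnonzero(labelled & (labels == lab))
            members = members[rng.permutation(len(members))]
            n_val = int(round(self.val_fraction * len(members)))
            n_val = min(n_val, max(len(members) - 1, 0))
            val_mask[members[:n_val]] = True
            train_mask[members[n_val:]] = True

        net = GATNetwork(feats.dim, cfg, labeling.n_classes)
        opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
        h = Tensor(feats.matrix)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        losses = []
        for _ in range(cfg.epochs):
            opt.zero_grad()
            logits = net.forward(h, src, dst, n, drop_rng)
            loss = masked_cross_entropy(logits, labels, train_mask)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        logits = net.forward(h, src, dst, n)
        pred = logits.data.argmax(-1)
        acc = (float((pred[val_mask] == labels[val_mask]).mean())
               if val_mask.any() else float("nan"))
        report = {"loss_history": losses, "final_loss": losses[-1],
                  "val_accuracy": acc, "n_train": int(train_mask.sum()),
                  "n_val": int(val_mask.sum())}
        self._export(net, h, src, dst, n, node_ids, "node_classification",
                     report)

    def _fit_link_prediction(self, g, feats, index, cfg):
        node_ids = list(index)
        n = len(node_ids)
        rng = np.random.default_rng(cfg.seed)
        edges = np.array([(index[c], index[p]) for c, p in g.edges()])
        perm = rng.permutation(len(edges))
        n_val = max(1, int(round(self.val_fraction * len(edges))))
        val_edges = edges[perm[:n_val]]
        train_edges = edges[perm[n_val:]]
        # message passing uses only training edges (no target leakage)
        pairs = {(int(a), int(b)) for a, b in train_edges}
        if self.bidirectional:
            pairs |= {(b, a) for a, b in pairs}
        pairs |= {(i, i) for i in range(n)}
        arr = np.array(sorted(pairs), dtype=np.int64)
        src, dst = arr[:, 0], arr[:, 1]

        net = GATNetwork(feats.dim, cfg, None)
        opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
        h = Tensor(feats.matrix)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        existing = {(int(a), int(b)) for a, b in edges}

        def sample_negatives(k: int, sampler) -> np.ndarray:
            neg = []
            while len(neg) < k:
                a, b = int(sampler.integers(n)), int(sampler.integers(n))
                if a != b and (a, b) not in existing:
                    neg.append((a, b))
            return np.array(neg)

        losses = []
        for _ in range(cfg.epochs):
            opt.zero_grad()
            z = net.embed(h, src, dst, n, drop_rng)
            neg = sample_negatives(len(train_edges), rng)
            u = np.concatenate([train_edges[:, 0], neg[:, 0]])
            v = np.concatenate([train_edges[:, 1], neg[:, 1]])
            y = np.concatenate([np.ones(len(train_edges)),
                                np.zeros(len(neg))])
            score = (z.gather(u) * z.gather(v)).sum(axis=-1)
            p = score.sigmoid()
            eps = 1e-9
            loss = -((Tensor(y) * (p + eps).log()
                      + Tensor(1.0 - y) * (1.0 - p + eps).log()).mean())
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        z = net.embed(h, src, dst, n)
        neg = sample_negatives(len(val_edges), np.random.default_rng(cfg.seed + 2))
        scores = np.concatenate([
            (z.data[val_edges[:, 0]] * z.data[val_edges[:, 1]]).sum(-1),
            (z.data[neg[:, 0]] * z.data[neg[:, 1]]).sum(-1)])
        y = np.concatenate([np.ones(len(val_edges)), np.zeros(len(neg))])
        auc = float(roc_auc_score(y, scores))
        report = {"loss_history": losses, "final_loss": losses[-1],
                  "val_auc": auc, "n_train_edges": int(len(train_edges)),
                  "n_val_edges": int(len(val_edges))}
        self._export(net, h, src, dst, n, node_ids, "link_prediction", report)

    def transform(self, node_ids: list[str] | None = None) -> np.ndarray:
        if not hasattr(self, "embeddings_"):
            raise ValueError("estimator is not fitted")
        if node_ids is None:
            return self.embeddings_.matrix
        return np.stack([self.embeddings_.vector(n) for n in node_ids])


# ------------------------------------------------------ functional wrappers

def train_gat_node_classification(g: OntologyGraph, feats: NodeFeatureTable,
                                  labeling: TopLevelLabeling,
                                  cfg: GatConfig | None = None):
    cfg = cfg or GatConfig()
    est = GATNodeEmbedder(task="node_classification", **_cfg_kwargs(cfg))
    est.fit(g, feats, labeling)
    return est.network_, est.embeddings_, est.report_


def train_gat_link_prediction(g: OntologyGraph, feats: NodeFeatureTable,
                              cfg: GatConfig | None = None):
    cfg = cfg or GatConfig()
    est = GATNodeEmbedder(task="link_prediction", **_cfg_kwargs(cfg))
    est.fit(g, feats)
    return est.network_, est.embeddings_, est.report_


def _cfg_kwargs(cfg: GatConfig) -> dict:
    return dict(n_layers=cfg.n_layers, n_heads=cfg.n_heads,
                hidden_dim=cfg.hidden_dim, embedding_dim=cfg.embedding_dim,
                dropout=cfg.dropout, epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay, seed=cfg.seed)
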