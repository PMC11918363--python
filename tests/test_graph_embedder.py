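"""Node feature assembly and GAT training on ontology graphs."""

import numpy as np
import pytest

from kgfuse.graph_embedder import (DegenerateTaskError, GatConfig, GATLayer,
                                   GATNodeEmbedder, NodeEmbeddingTable,
                                   NodeFeatureTable, assemble_node_text,
                                   message_passing_edges,
                                   train_gat_node_classification)
from kgfuse.ontology import OntologyClass, assign_top_level_labels
from kgfuse.synthetic_data import OntologySpec, generate_ontology


def branch_features(g, labeling, dim=16, seed=0, signal=3.0):
    """Features with a branch-specific offset (separable task)."""
    nodes = g.nodes()
    X = np.random.default_rng(seed).normal(0, 1, (len(nodes), dim))
    for i, n in enumerate(nodes):
        if n != g.root:
            X[i, labeling.labels[n] % dim] += signal
    return NodeFeatureTable(node_ids=nodes, matrix=X)


@pytest.fixture(scope="module")
def tree200():
    g = generate_ontology(OntologySpec(n_classes=200, n_top=2, seed=1))
    return g, assign_top_level_labels(g)


def test_assemble_node_text_order_and_separator():
    cls = OntologyClass(id="S:1", label="Drowsiness",
                        synonyms=["drowsy", "sleepiness"],
                        definition="reduced wakefulness")
    assert assemble_node_text(cls) == \
        "Drowsiness [SEP] drowsy [SEP] sleepiness [SEP] reduced wakefulness"
    assert assemble_node_text(OntologyClass(id="X", label="Pain")) == "Pain"
    assert assemble_node_text(OntologyClass(id="SYMP:0000001")) == \
        "SYMP:0000001"


def test_gat_attention_normalizes_per_neighborhood(rng, tree200):
    g, _ = tree200
    index = {n: i for i, n in enumerate(g.nodes())}
    src, dst = message_passing_edges(g, index)
    layer = GATLayer(8, 4, 2, rng)
    from kgfuse._tensor import Tensor, segment_sum
    h = Tensor(rng.normal(0, 1, (len(index), 8)))
    _, att = layer.attention(h, src, dst, len(index))
    sums = segment_sum(att, dst, len(index))
    assert np.allclose(sums.data, 1.0)


def test_separable_ontology_high_heldout_accuracy(tree200):
    g, lab = tree200
    feats = branch_features(g, lab)
    est = GATNodeEmbedder(epochs=80, seed=0).fit(g, feats, lab)
    assert est.report_["val_accuracy"] >= 0.9
    assert est.embeddings_.dim == est.embedding_dim
    assert len(est.embeddings_.node_ids) == g.n_nodes


def test_permuted_label_null_stays_near_majority(tree200):
    """Shuffling labels severs both the feature and the structure channel;
    held-out accuracy must then hover at the majority rate."""
    from kgfuse.ontology import TopLevelLabeling
    g, lab = tree200
    nodes = [n for n in g.nodes() if n != g.root]
    y = np.array([lab.labels[n] for n in nodes])
    maj = np.bincount(y).max() / len(y)
    accs = []
    for seed in range(3):
        perm = np.random.default_rng(seed).permutation(len(y))
        shuffled = TopLevelLabeling(
            labels={n: int(y[perm[i]]) for i, n in enumerate(nodes)},
            n_classes=lab.n_classes)
        feats = branch_features(g, lab, seed=seed)
        est = GATNodeEmbedder(epochs=60, seed=seed).fit(g, feats, shuffled)
        accs.append(est.report_["val_accuracy"])
    assert abs(float(np.mean(accs)) - maj) < 0.15


def test_zero_learning_rate_keeps_initial_forward(tree200):
    g, lab = tree200
    feats = branch_features(g, lab)
    a = GATNodeEmbedder(epochs=1, learning_rate=0.0, dropout=0.0,
                        seed=4).fit(g, feats, lab)
    b = GATNodeEmbedder(epochs=5, learning_rate=0.0, dropout=0.0,
                        seed=4).fit(g, feats, lab)
    assert np.array_equal(a.embeddings_.matrix, b.embeddings_.matrix)


def test_node_classification_is_bit_reproducible(tree200):
    g, lab = tree200
    feats = branch_features(g, lab)
    runs = [GATNodeEmbedder(epochs=15, seed=9).fit(g, feats, lab)
            for _ in range(2)]
    assert np.array_equal(runs[0].embeddings_.matrix,
                          runs[1].embeddings_.matrix)
    assert runs[0].report_["loss_history"] == runs[1].report_["loss_history"]


def test_degenerate_single_class_rejected():
    g = generate_ontology(OntologySpec(n_classes=20, n_top=1, seed=2))
    lab = assign_top_level_labels(g)
    feats = branch_features(g, lab)
    with pytest.raises(DegenerateTaskError):
        GATNodeEmbedder(epochs=1).fit(g, feats, lab)


def test_link_prediction_beats_chance_and_covers_all_nodes():
    g = generate_ontology(OntologySpec(n_classes=200, n_top=3, seed=5))
    lab = assign_top_level_labels(g)
    aucs = []
    for seed in range(5):
        feats = branch_features(g, lab, seed=seed)
        est = GATNodeEmbedder(task="link_prediction", epochs=40,
                              seed=seed).fit(g, feats)
        aucs.append(est.report_["val_auc"])
        assert est.embeddings_.matrix.shape[0] == g.n_nodes
        assert est.embeddings_.provenance == "link_prediction"
    assert float(np.mean(aucs)) > 0.5


def test_link_prediction_reproducible():
    g = generate_ontology(OntologySpec(n_classes=60, n_top=3, seed=6))
    feats = branch_features(g, assign_top_level_labels(g))
    a = GATNodeEmbedder(task="link_prediction", epochs=10, seed=1).fit(g, feats)
    b = GATNodeEmbedder(task="link_prediction", epochs=10, seed=1).fit(g, feats)
    assert np.array_equal(a.embeddings_.matrix, b.embeddings_.matrix)


def test_embedding_table_round_trip(tmp_path, tree200):
    g, lab = tree200
    feats = branch_features(g, lab)
    _, table, _ = train_gat_node_classification(
        g, feats, lab, GatConfig(epochs=5, seed=0))
    table.save(tmp_path / "emb")
    back = NodeEmbeddingTable.load(tmp_path / "emb")
    assert back.node_ids == table.node_ids
    assert np.array_equal(back.matrix, table.matrix)  # lossless (repr floats)
    assert back.provenance == table.provenance


def test_gat_config_validation():
    with pytest.raises(ValueError):
        GatConfig(dropout=1.0)
    with pytest.raises(ValueError):
        GatConfig(n_layers=0)
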