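"""Wordpiece-aligned knowledge injection and the graph concat model."""

import numpy as np
import pytest

from kgfuse._tensor import Tensor
from kgfuse.encoder import TinyTransformerEncoder, WordPieceTokenizer
from kgfuse.entity_tagger import TaggedSequence, TaggedSpan, build_lexicon, tag
from kgfuse.fusion_ner import (FusionNERModel, KnowledgeVector, VariantConfig,
                               align_knowledge, fuse, subgraph_pool)
from kgfuse.graph_embedder import (GATNetwork, GatConfig, NodeEmbeddingTable,
                                   NodeFeatureTable)
from kgfuse.nn import AdamW
from kgfuse._tensor import masked_cross_entropy
from kgfuse.synthetic_data import OntologySpec, generate_ontology


@pytest.fixture(scope="module")
def tok():
    return WordPieceTokenizer.train(
        ["very drowsy and tired", "no pain relief at all",
         "unbelievable discomfort happened"], vocab_size=48)


def table(node_ids, dim=4, seed=0):
    m = np.random.default_rng(seed).normal(0, 1, (len(node_ids), dim))
    return NodeEmbeddingTable(node_ids=list(node_ids), matrix=m)


def test_pivot_gets_embedding_rest_zero(tok):
    # one tagged word split into several pieces: [e, 0, 0, ...]
    words = ["unbelievable"]
    enc = tok.encode_words(words, max_len=32)
    lo, hi = enc.word_to_pieces[0]
    assert hi - lo >= 3
    ts = TaggedSequence(tokens=words,
                        spans=[TaggedSpan(0, 0, "N:1", "symptom")])
    emb = table(["N:1"])
    v = align_knowledge(ts, emb, enc).v_aligned
    assert np.array_equal(v[lo], emb.vector("N:1"))
    nz = np.flatnonzero(np.abs(v).sum(axis=1))
    assert nz.tolist() == [lo]


def test_untagged_sentence_gives_all_zeros(tok):
    words = "no pain at all".split()
    enc = tok.encode_words(words, max_len=16)
    v = align_knowledge(TaggedSequence(tokens=words, spans=[]),
                        table(["N:1"]), enc).v_aligned
    assert not v.any()


def test_padding_positions_are_zero(tok):
    words = ["drowsy", "and", "tired"]
    enc = tok.encode_words(words, max_len=16, pad_to=16)
    ts = TaggedSequence(tokens=words, spans=[
        TaggedSpan(0, 0, "N:1", "symptom"), TaggedSpan(2, 2, "N:2", "symptom")])
    v = align_knowledge(ts, table(["N:1", "N:2"]), enc).v_aligned
    last_real = enc.word_to_pieces[-1][1]  # [SEP] follows
    assert not v[last_real + 1:].any()


def test_multiword_span_puts_embedding_on_each_word_pivot(tok):
    words = "no pain relief at all".split()
    enc = tok.encode_words(words, max_len=16)
    ts = TaggedSequence(tokens=words,
                        spans=[TaggedSpan(1, 2, "N:4", "symptom")])
    emb = table(["N:4"])
    v = align_knowledge(ts, emb, enc).v_aligned
    pivots = [enc.word_to_pieces[w][0] for w in (1, 2)]
    for p in pivots:
        assert np.array_equal(v[p], emb.vector("N:4"))
    assert len(np.flatnonzero(np.abs(v).sum(axis=1))) == 2


def test_missing_node_raises_lookup_error_naming_it(tok):
    words = ["drowsy"]
    enc = tok.encode_words(words, max_len=8)
    ts = TaggedSequence(tokens=words, spans=[TaggedSpan(0, 0, "GHOST", "drug")])
    with pytest.raises(KeyError, match="GHOST"):
        align_knowledge(ts, table(["N:1"]), enc)


def test_fuse_dimensions_and_identity_block():
    T = np.random.default_rng(0).normal(0, 1, (10, 768))
    v = KnowledgeVector(v_aligned=np.zeros((10, 128)))
    fused = fuse(T, v)
    assert fused.T_tilde.shape == (10, 896)
    assert np.array_equal(fused.T_tilde[:, :768], T)
    with pytest.raises(ValueError):
        fuse(T, KnowledgeVector(v_aligned=np.zeros((9, 128))))


def test_fuse_is_position_equivariant():
    rng = np.random.default_rng(1)
    T = rng.normal(0, 1, (6, 5))
    v = rng.normal(0, 1, (6, 3))
    perm = rng.permutation(6)
    a = fuse(T, KnowledgeVector(v))
    b = fuse(T[perm], KnowledgeVector(v[perm]))
    assert np.array_equal(a.T_tilde[perm], b.T_tilde)


@pytest.fixture(scope="module")
def small_graph_setup():
    g = generate_ontology(OntologySpec(n_classes=30, n_top=3, seed=2))
    nodes = g.nodes()
    feats = NodeFeatureTable(
        node_ids=nodes,
        matrix=np.random.default_rng(0).normal(0, 1, (len(nodes), 8)))
    gat = GATNetwork(8, GatConfig(embedding_dim=4, dropout=0.0, seed=0),
                     n_classes=None)
    return g, feats, gat


def test_subgraph_pool_max_mean_concatenation(small_graph_setup):
    g, feats, gat = small_graph_setup
    cfg = VariantConfig("adaptive_subgraph", k=2)
    node = [n for n in g.nodes() if n != g.root][0]
    pooled = subgraph_pool(g, node, cfg, gat, feats)
    d = gat.cfg.embedding_dim
    assert pooled.shape == (2 * d,)
    # recompute max/mean directly from the subgraph embedding
    from kgfuse.fusion_ner import khop_subgraph
    members, src, dst = khop_subgraph(g, node, 2)
    rows = [feats.node_ids.index(m) for m in members]
    z = gat.embed(Tensor(feats.matrix[rows]), src, dst, len(members))
    assert np.allclose(pooled.data[:d], z.data.max(axis=0))
    assert np.allclose(pooled.data[d:], z.data.mean(axis=0))


def test_pooled_output_invariant_to_node_order():
    # forced example: representations [[1,2],[3,0]] -> pooled [3,2,2,1]
    z = Tensor(np.array([[1.0, 2.0], [3.0, 0.0]]))
    from kgfuse._tensor import concatenate
    pooled = concatenate([z.max(axis=0), z.mean(axis=0)], axis=-1)
    assert pooled.data.tolist() == [3.0, 2.0, 2.0, 1.0]
    z2 = Tensor(z.data[::-1].copy())
    pooled2 = concatenate([z2.max(axis=0), z2.mean(axis=0)], axis=-1)
    assert np.array_equal(pooled.data, pooled2.data)


def _batch(tok, lexicon_nodes, tagged=True):
    words = "very drowsy and tired and no pain relief at all .".split()
    enc = tok.encode_words(words, max_len=32)
    spans = ([TaggedSpan(1, 1, lexicon_nodes[0], "symptom")]
             if tagged else [])
    return [enc], [TaggedSequence(tokens=words, spans=spans)], [len(words)]


def _fixed_model(tok, dim=4, seed=0, zero_table=False, head_dropout=0.1):
    encoder = TinyTransformerEncoder(tok.vocab_size, hidden_size=16,
                                     n_layers=1, seed=seed)
    ids = ["N:1", "N:2"]
    emb = table(ids, dim=dim)
    if zero_table:
        emb = NodeEmbeddingTable(node_ids=ids,
                                 matrix=np.zeros((len(ids), dim)))
    from kgfuse.entity_tagger import Lexicon
    lex = Lexicon(entries={"drowsy": "N:1", "tired": "N:2"},
                  source="symptom", max_len=1)
    return FusionNERModel(encoder, tok, lexicon=lex,
                          cfg=VariantConfig("fixed"), embedding_table=emb,
                          head_dropout=head_dropout, seed=seed)


def test_forward_logits_have_three_classes(tok):
    model = _fixed_model(tok)
    encs, tagged, _ = _batch(tok, ["N:1"])
    logits = model.forward(encs, tagged)
    assert logits.shape == (1, len(encs[0].piece_ids), 3)


def test_fixed_variant_gnn_is_frozen_under_training_step(tok):
    model = _fixed_model(tok)
    before = model.gnn_parameter_checksum()
    encs, tagged, _ = _batch(tok, ["N:1"])
    opt = AdamW(model.parameters(), lr=1e-2)
    logits = model.forward(encs, tagged, np.random.default_rng(0))
    labels = np.zeros(logits.shape[:2], dtype=int)
    mask = np.ones(logits.shape[:2])
    masked_cross_entropy(logits, labels, mask).backward()
    opt.step()
    assert model.gnn_parameter_checksum() == before


def test_adaptive_variant_gnn_receives_gradient(tok, small_graph_setup):
    g, feats, gat = small_graph_setup
    lex = build_lexicon(g)
    encoder = TinyTransformerEncoder(tok.vocab_size, hidden_size=16,
                                     n_layers=1, seed=0)
    model = FusionNERModel(encoder, tok, lexicon=lex,
                           cfg=VariantConfig("adaptive"), graph=g, gat=gat,
                           feats=feats, head_dropout=0.0, seed=0)
    words = ["very", g.cls(g.nodes()[5]).label.split()[0], "happened", "."]
    enc = tok.encode_words(words, max_len=24)
    tagged = model.tag_words(words)
    assert tagged.spans, "sanity: the lexicon must fire on the label word"
    before = model.gnn_parameter_checksum()
    opt = AdamW(model.parameters(), lr=1e-2)
    logits = model.forward([enc], [tagged])
    labels = np.zeros(logits.shape[:2], dtype=int)
    masked_cross_entropy(logits, labels, np.ones(logits.shape[:2])).backward()
    opt.step()
    assert model.gnn_parameter_checksum() != before


def test_zero_table_matches_baseline_encoder_states(tok):
    fused_model = _fixed_model(tok, zero_table=True, head_dropout=0.0)
    encoder_b = TinyTransformerEncoder(tok.vocab_size, hidden_size=16,
                                       n_layers=1, seed=0)
    baseline = FusionNERModel(encoder_b, tok, head_dropout=0.0, seed=0)
    encs, tagged, _ = _batch(tok, ["N:1"])
    # same seed -> identical encoders; zero table -> zero knowledge block
    ids = np.stack([encs[0].piece_ids])
    mask = np.stack([encs[0].attention_mask])
    T_f = fused_model.encoder(ids, mask).data
    T_b = baseline.encoder(ids, mask).data
    assert np.array_equal(T_f, T_b)
    v = fused_model._knowledge_block(encs, tagged, 1, ids.shape[1], None)
    assert not v.data.any()


def test_nonzero_positions_equal_tagged_word_pivots(tok):
    rng = np.random.default_rng(7)
    g = generate_ontology(OntologySpec(n_classes=40, n_top=4, seed=3))
    lex = build_lexicon(g)
    emb = table(g.nodes(), dim=6, seed=1)
    vocab_words = [g.cls(n).label for n in g.nodes()][1:]
    for _ in range(50):
        words = []
        for _ in range(int(rng.integers(3, 10))):
            if rng.random() < 0.4:
                words.extend(vocab_words[int(rng.integers(
                    len(vocab_words)))].split())
            else:
                words.append("filler")
        enc = tok.encode_words(words, max_len=64)
        ts = tag(words, lex)
        v = align_knowledge(ts, emb, enc).v_aligned
        expect = sorted({enc.word_to_pieces[w][0]
                         for sp in ts.spans
                         for w in range(sp.start, sp.end + 1)
                         if enc.word_to_pieces[w][1] > enc.word_to_pieces[w][0]})
        assert np.flatnonzero(np.abs(v).sum(axis=1)).tolist() == expect


def test_variant_config_validation():
    with pytest.raises(ValueError):
        VariantConfig("fixed", k=2)
    with pytest.raises(ValueError):
        VariantConfig("bogus")
    assert VariantConfig("adaptive_subgraph").k == 2
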