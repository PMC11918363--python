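"""Desk-scale benchmark experiments run entirely on synthetic data.

Two drivers used by the test suite and the reproduction script:

``knowledge_advantage`` — the headline simulation: on corpora where ADE
spans are symptom-lexicon phrases adjacent to drug mentions (p_signal 0.9)
and only half of the test symptom surface forms occur in training, a graph
concat model with fixed GNN weights is compared against the identical
knowledge-free baseline, both with a tiny from-scratch transformer encoder.
The baseline can only memorize the training-pool surfaces; the fusion model
receives unseen surfaces through the lexicon and embedding table.

``end_to_end`` — one seeded simulate -> embed -> train -> evaluate pipeline
returning the strict test report; running it twice with the same seed must
give identical results.
"""

from __future__ import annotations

import logging

import numpy as np

from .encoder import TinyTransformerEncoder, WordPieceTokenizer
from .entity_tagger import build_lexicon, merge_lexicons
from .evaluation import EvalReport, strict_prf
from .graph_embedder import (GATNodeEmbedder, assemble_node_text,
                             encode_node_features)
from .ontology import assign_top_level_labels, combine_graphs
from .synthetic_data import (CorpusSpec, benchmark_graphs, generate_corpus,
                             make_fusion_benchmark)
from .training import (FusionNERTagger, SplitSpec, make_examples,
                       predict_spans, split_dataset)

logger = logging.getLogger(__name__)

__all__ = ["knowledge_advantage", "end_to_end"]

# benchmark-scale settings (see docs/methods.md for rationale)
GAT_EPOCHS = 60
GAT_DIM = 32
FEATURE_DIM = 32


def _graph_embeddings(g_drug, g_symp, seed: int):
    """Combined knowledge graph, its lexicon-free feature pipeline and the
    node-classification GAT embeddings."""
    g = combine_graphs(g_drug, g_symp)
    texts = [assemble_node_text(g.cls(n)) for n in g.nodes()]
    tok = WordPieceTokenizer.train(texts, vocab_size=600, min_freq=1)
    encoder = TinyTransformerEncoder(tok.vocab_size, hidden_size=FEATURE_DIM,
                                     seed=seed)
    feats = encode_node_features(g, encoder, tok)
    emb = GATNodeEmbedder(epochs=GAT_EPOCHS, embedding_dim=GAT_DIM,
                          seed=seed)
    emb.fit(g, feats, assign_top_level_labels(g))
    return g, emb.embeddings_


def knowledge_advantage(base_seed: int = 0, n_seeds: int = 5,
                        p_signal: float = 0.9, overlap: float = 0.5) -> dict:
    """Mean strict test F1 of graph concat (fixed) vs the knowledge-free
    baseline over ``n_seeds`` replicates.

    Returns per-seed scores and the mean advantage in F1 points.
    """
    baseline_f1, fusion_f1 = [], []
    for i in range(n_seeds):
        seed = base_seed + i
        bench = make_fusion_benchmark(
            seed=seed, overlap=overlap,
            corpus_spec=CorpusSpec(p_signal=p_signal))
        _, emb = _graph_embeddings(bench["g_drug"], bench["g_symp"], seed)
        for variant, scores, kw in (
                ("baseline", baseline_f1, {}),
                ("fixed", fusion_f1, {"lexicon": bench["lexicon"],
                                      "embedding_table": emb})):
            est = FusionNERTagger(variant=variant, seed=seed, **kw)
            est.fit(bench["train_docs"], bench["val_docs"])
            f1 = est.score(bench["test_docs"])
            scores.append(f1)
            logger.info("seed %d %s strict test F1 %.2f", seed, variant, f1)
    return {
        "baseline_f1": baseline_f1,
        "fusion_f1": fusion_f1,
        "baseline_mean": float(np.mean(baseline_f1)),
        "fusion_mean": float(np.mean(fusion_f1)),
        "advantage": float(np.mean(fusion_f1) - np.mean(baseline_f1)),
    }


def end_to_end(seed: int = 0, n_docs: int = 60) -> EvalReport:
    """Seeded simulate -> embed -> train -> evaluate pipeline (fixed
    variant); strict span report on the held-out test split."""
    g_drug, g_symp = benchmark_graphs(seed)
    corpus = generate_corpus(
        g_drug, g_symp,
        CorpusSpec(n_docs=n_docs, p_signal=0.9, seed=seed * 11 + 3))
    train_docs, val_docs, test_docs = split_dataset(corpus,
                                                    SplitSpec(seed=seed))
    _, emb = _graph_embeddings(g_drug, g_symp, seed)
    lexicon = merge_lexicons(build_lexicon(g_drug, "drug"),
                             build_lexicon(g_symp, "symptom"))
    est = FusionNERTagger(variant="fixed", lexicon=lexicon,
                          embedding_table=emb, epochs=4, seed=seed)
    est.fit(train_docs, val_docs)
    gold, pred = predict_spans(est.model_, make_examples(test_docs))
    return strict_prf(gold, pred)
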