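# kgfuse — knowledge-graph fusion for adverse-drug-event span detection

Patient reports on social media, forums and drug labels are a major source
of post-market drug-safety signals, but adverse drug events (ADEs) in them
are written in informal, highly variable language.  `kgfuse` implements a
knowledge-fusion pipeline for extracting ADE spans from such text as a
named-entity-recognition problem, aimed at pharmacovigilance/NLP
researchers: structured knowledge about drugs and symptoms (from ontologies
such as a drug ontology built on ATC, or the public symptom ontology) is
injected into a transformer sequence labeler, so the model can recognize
symptom and drug mentions it never saw during fine-tuning.

## The model

1. **Ontology → graph.** An ontology (OWL RDF/XML or OBO) becomes a
   directed class graph: nodes *V* are the named classes, edges *E* the
   asserted subclass relations (all other logical axioms ignored).  Two
   ontologies are combined into one knowledge graph by a single bridging
   edge between their roots.
2. **Node embeddings.** Each class's annotations (label, synonyms,
   definition) are embedded with a contextual text encoder into a fixed
   node feature vector; a graph attention network (GAT) is trained to
   predict each node's top-level branch (or, alternatively, on link
   prediction), and its last hidden layer supplies node embeddings of width
   d_G.
3. **Rule-based tagging.** A lexicon built from all class labels and
   synonyms marks drug/symptom mentions in the input by greedy longest
   match.
4. **Fusion (the *graph concat* model).** For a sentence with transformer
   states T (one per wordpiece), a knowledge vector ṽ holds each tagged
   word's node embedding at its pivotal (first) wordpiece and zeros
   everywhere else — remaining pieces, untagged words, special tokens,
   padding.  The fused representation T̃ = [T ; ṽ] feeds a linear head with
   three output neurons (IOB).  GNN weights are frozen (*fixed*), trained
   jointly (*adaptive weights*), or replaced by pooled k-hop subgraph
   representations (global max ‖ mean, *adaptive weights + subgraph*).
5. **Protocol & scoring.** Document-level 64/16/20 train/validation/test
   splits, AdamW with token-level cross-entropy (subword positions beyond a
   word's first piece are masked), TPE-style Bayesian hyperparameter search
   maximizing validation F1, final refit on train+validation, and strict
   span-level precision/recall/F1 (exact extent match; a relaxed
   one-token-overlap mode is also provided).

Everything runs on one CPU: the package ships a compact numpy
autodifferentiation engine with a tiny from-scratch transformer encoder and
GAT, plus a synthetic-data generator producing ontologies and annotated
corpora with controllable ADE/lexicon co-occurrence, so the full pipeline
is testable without any licensed corpus or pretrained checkpoint.

## Worked example

```python
from kgfuse import (OntologyClass, OntologyGraph, assign_top_level_labels,
                    build_lexicon, tag)

classes = {
    "SYMP:0": OntologyClass(id="SYMP:0", label="symptom"),
    "SYMP:1": OntologyClass(id="SYMP:1", label="Drowsiness",
                            synonyms=["drowsy"], parents=["SYMP:0"]),
    "SYMP:2": OntologyClass(id="SYMP:2", label="Tiredness",
                            synonyms=["tired"], parents=["SYMP:0"]),
    "SYMP:3": OntologyClass(id="SYMP:3", label="Pain", parents=["SYMP:0"]),
}
g = OntologyGraph(classes)
print(f"graph: |V|={g.n_nodes} |E|={g.n_edges} root={g.root}")
labeling = assign_top_level_labels(g)
print(f"top-level classes: {labeling.n_classes}")

lexicon = build_lexicon(g, source="symptom")
tokens = "Very drowsy and tired and no pain relief at all .".split()
for span in tag(tokens, lexicon).spans:
    print(span.start, span.end, tokens[span.start], "->", span.node)
```

prints

```
graph: |V|=4 |E|=3 root=SYMP:0
top-level classes: 3
1 1 drowsy -> SYMP:1
3 3 tired -> SYMP:2
6 6 pain -> SYMP:3
```

i.e. the tagger anchors three symptom mentions to their ontology nodes;
those are the positions where the fusion model will inject node embeddings.
A complete experiment — synthetic ontologies and corpora, GAT embeddings,
then the knowledge-free baseline against the fixed-weight graph concat
model:

```python
from kgfuse import (GATNodeEmbedder, FusionNERTagger, TinyTransformerEncoder,
                    WordPieceTokenizer, assemble_node_text,
                    assign_top_level_labels, combine_graphs,
                    encode_node_features)
from kgfuse.synthetic_data import make_fusion_benchmark

bench = make_fusion_benchmark(seed=0)          # ontologies + corpora
g = combine_graphs(bench["g_drug"], bench["g_symp"])
print(f"combined KG: |V|={g.n_nodes} |E|={g.n_edges}")

texts = [assemble_node_text(g.cls(n)) for n in g.nodes()]
tok = WordPieceTokenizer.train(texts, vocab_size=600, min_freq=1)
feats = encode_node_features(
    g, TinyTransformerEncoder(tok.vocab_size, hidden_size=32, seed=0), tok)
gat = GATNodeEmbedder(epochs=60, embedding_dim=32, seed=0)
gat.fit(g, feats, assign_top_level_labels(g))

for variant, kw in [("baseline", {}),
                    ("fixed", dict(lexicon=bench["lexicon"],
                                   embedding_table=gat.embeddings_))]:
    est = FusionNERTagger(variant=variant, seed=0, **kw)
    est.fit(bench["train_docs"], bench["val_docs"])
    print(f"{variant:8s} strict test F1 = {est.score(bench['test_docs']):.2f}")
```

prints (about 25 s on one CPU)

```
combined KG: |V|=380 |E|=379
baseline strict test F1 = 20.90
fixed    strict test F1 = 50.70
```

Half of the test corpus's symptom surface forms never occur in training, so
the from-scratch baseline can only score on memorized surfaces, while the
fusion model recognizes unseen symptoms through the lexicon and the node
embeddings — a ~30-point strict-F1 gap at this scale.  `FusionNERTagger`
and `GATNodeEmbedder` are scikit-learn-style estimators
(`get_params`/`set_params`, fitted attributes `model_`, `embeddings_`,
`history_`, `report_`).

A `kgfuse` console script exposes the pipeline
(`graph build/combine`, `embed`, `tag`, `simulate ontology/corpus`,
`train`, `eval`, `stats`); see `kgfuse --help`.

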