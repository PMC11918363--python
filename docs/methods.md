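# Methods

## Problem and model

`kgfuse` treats adverse-drug-event (ADE) extraction as three-class IOB
sequence labelling over wordpieces, enriched with ontology knowledge.  The
pipeline has four stages, each an importable module:

**Ontology graphs** (`kgfuse.ontology`).  An ontology is reduced to a
directed class graph: one node per named class, one child→parent edge per
asserted subclass axiom; all other logical axioms are ignored, so the graph
of a well-formed ontology is an acyclic, weakly connected tree-like
structure with a single root.  Obsolete classes are dropped on load because
they carry no usable annotation text.  Classes with several subclass
parents are permitted (the graph becomes a DAG); any path-dependent rule
then follows the lexicographically smallest parent so results do not depend
on assertion order.  Ontologies with several parentless classes are
rejected unless an explicit virtual root is configured.  Two graphs are
combined by uniting nodes and edges and adding exactly one bridging edge
that makes the second root a child of the first, so |V| = |V₁|+|V₂| and
|E| = |E₁|+|E₂|+1.  Top-level labelling assigns each node the child-of-root
branch it descends from; in a combined graph a bridged former root is not
itself a class but expands into its own children, so two 14-branch
ontologies yield a 28-class label space (the bridged root node itself
adopts its first child's branch so the labels still partition all non-root
nodes).

**Node embeddings** (`kgfuse.graph_embedder`).  Each class is rendered to
text — label, synonyms, definition, joined by a separator token, falling
back to the identifier when all are empty — and embedded by mean-pooling
the final-layer wordpiece states of a contextual encoder (mean pooling is
the deterministic sentence-embedding default).  A multi-head graph
attention network is trained on top: per-edge scores
e_ij = LeakyReLU(a_s·Wh_i + a_d·Wh_j) are softmax-normalised over each
target's in-neighborhood, hidden layers concatenate heads, the output layer
averages them.  Edges are symmetrised for message passing (a directed
child→parent tree would starve leaf-ward information flow; a flag disables
this) and self-loops are added.  The supervised task is either node
classification against the top-level labels (stratified 80/20 node split)
or link prediction with dot-product edge scoring against 1:1 uniformly
sampled negative pairs, message-passing only over training edges.  Exported
node embeddings are the last hidden layer before the task head.

**Tagging and fusion** (`kgfuse.entity_tagger`, `kgfuse.fusion_ner`).  The
lexicon maps every normalized class label/synonym (lowercase, surrounding
punctuation stripped, whitespace collapsed — deliberately no stemming, to
avoid false positives) to its node.  Synonym collisions resolve to the
shallower node, then the smaller identifier; when drug and symptom lexicons
merge, drug wins a shared surface.  Tagging is greedy left-to-right longest
match over token n-grams within a sentence.  For fusion, each tagged word's
node embedding is placed at the word's pivotal (first) wordpiece; remaining
pieces, untagged words, special tokens and padding are zero rows.  Every
word of a multi-word tagged span receives the span's embedding at its own
pivot.  The fused per-position representation [T ; ṽ] (width d_T + d_G)
passes through dropout (default 0.1) into a linear 3-way head.  Variants:
*fixed* — the embedding table is a constant lookup, no gradient reaches any
GNN parameter; *adaptive* — the GAT runs inside the training graph and its
weights update; *adaptive subgraph* — the k-hop neighborhood (default
k = 2, direction-ignored) of each tagged node is run through the GAT and
pooled by concatenated global max and mean, giving a 2·d_G block.  A model
constructed without a knowledge source is the knowledge-free baseline with
identical encoder and head geometry.

**Protocol and evaluation** (`kgfuse.training`, `kgfuse.evaluation`).
Splits are at document level (posts/reports), 20% test, remainder 4:1
train:validation (64/16/20 overall), round-half-up on the test count first.
Training minimizes token-level cross-entropy with AdamW; the word label
sits on its first wordpiece and all other pieces are masked out of the
loss; the best-validation-F1 epoch checkpoint is kept (no early stopping).
Hyperparameter search is a sequential model-based (TPE-style) sampler:
random start-up trials, then per-parameter kernel-density models of the
top-γ and remaining trials, choosing the candidate maximizing the density
ratio; the default space is lr ∈ [1e-5, 1e-4] log-uniform,
batch ∈ {8,16,32}, epochs ∈ [2,10], weight decay ∈ [0,0.1], head dropout ∈
[0,0.3], 20 trials.  The final model retrains from scratch on
train+validation, guarded against test-document leakage.  Evaluation
discards IOB and aggregates maximal B I* runs into spans (an orphan I
following O or at sequence start opens a span — the standard conlleval
repair; documented because it changes counts on malformed predictions).
Strict scores require exact extent identity; relaxed scores credit ≥1-token
same-sentence overlap with one-to-one greedy matching by overlap size then
left position so duplicates cannot double-credit.  Micro-averaging over all
spans is the default (a macro helper exists).  Duplicate identical spans
collapse (sets).  Corpus characterization reports, averaged per sentence:
unique/total wordpieces (diversity), wordpiece count (length), and
lexicon-tagged mentions (knowledge-graph hits).

## Numerical stack

No GPU framework is used: `kgfuse._tensor` is a compact reverse-mode
autodifferentiation engine over float64 numpy arrays (matmul, reductions,
segment softmax/sum for sparse attention, fused masked cross-entropy), and
`kgfuse.nn` provides Glorot-initialised linear layers, post-LN transformer
blocks and bias-corrected AdamW with decoupled weight decay.  Gradients of
every op are tested against central finite differences.  All randomness
flows through explicit `numpy.random.Generator` objects, so identically
seeded runs are bit-identical on CPU.  The tiny encoder
(`TinyTransformerEncoder`) mirrors the BERT interface at reduced scale; the
test/benchmark configuration is hidden 32, 2 layers, 2 heads, FFN 64,
max 64 wordpieces.  The WordPiece-style tokenizer is trained on the corpus
at hand (frequent words, short prefix/suffix pieces, and always all
letters/digits, so unseen words decompose instead of collapsing to
`[UNK]`).

## Synthetic data: what it emulates, and what it does not

`kgfuse.synthetic_data` generates (a) tree ontologies — the root has
exactly `n_top` children, every other class attaches uniformly at random;
labels/synonyms are unique 1–2-word phrases of pronounceable pseudo-words —
and (b) patient-report-style documents.  Per sentence: filler words
(vocabulary 2,000); with probability `p_ade_sentence` (0.6) an ADE event
that is, with probability `p_signal`, a symptom-lexicon phrase in the same
sentence as a drug mention, and otherwise an out-of-lexicon phrase; with
probability `p_distractor` (0.3) a drug-free symptom mention that is *not*
an ADE; optional casing/typo noise on fillers (`noise_rate`, 0.05).  The
ADE label therefore depends on lexicon membership *plus* a local drug cue,
not on membership alone — this is what makes the knowledge-advantage
experiment falsifiable: a tagger hit is informative but not sufficient.

The benchmark setup (`make_fusion_benchmark`) uses a 320-class symptom
ontology (≥300 symptom phrases), a 60-class drug ontology, and 80/20/40
train/validation/test documents of ~3 sentences; the test corpus draws its
symptom classes from a pool that overlaps the training pool at a controlled
fraction (default 0.5), so a model without the lexicon cannot have
memorized half of the test symptom vocabulary.  These sizes were fixed once
as the smallest scale at which the training dynamics are stable across
seeds.

What generated corpora do **not** emulate: real Twitter orthography beyond
simple noise, discontinuous or overlapping gold mentions, annotation
disagreement, genuine linguistic context (fillers are unordered), and
pretrained-encoder effects (all encoders here train from scratch).  Passing
the simulation therefore demonstrates that the fusion machinery works and
that injected knowledge is usable by the head — not that the printed
F1 levels transfer to CADEC-class corpora.

## Design choices where the design was open

- Pivotal wordpiece = the word's first subword; the node embedding precedes
  the zero rows of the remaining pieces.
- GAT defaults: 2 layers, 4 heads, hidden 64, d_G 128 (benchmarks use
  d_G 32 and 60 epochs for speed), dropout 0.2, 200 epochs, lr 5e-3 — small
  enough for a single CPU, deep enough for 2-hop propagation.
- NER training defaults at tiny-encoder scale: lr 2e-3, batch 16, 8 epochs,
  weight decay 0.01, 10% linear warmup.
- Tagging operates within sentences only; no abbreviation expansion.
- Discontinuous character-offset annotations collapse to their covering
  token range by default (a flag drops them instead); only the ADE type is
  the NER target, other gold types are carried through untouched.
- Hyperparameter search is tuned per experiment, not shared across
  experiments.

## Degenerate inputs and numerical conventions

Empty ontologies yield empty lexicons (warning, not error); a one-class
supervised label space is a degenerate-task error; precision/recall with an
empty denominator score 0 (hence F1 = 0 when either set is empty);
zero-length character spans are rejected; sentences longer than the encoder
maximum are truncated with a logged warning (affected words get an empty
piece range and drop out of loss and alignment); segment softmax subtracts
the per-segment maximum for stability; attention masking uses a −1e9
additive bias.

## Known limitations

- A **transductive caveat** on the GAT sanity null: with iid random node
  features, held-out node-classification accuracy stays far *above* the
  majority rate (~0.95 vs ~0.58 on a 200-node, 2-branch tree).  This is not
  a defect of training but a property of transductive node classification
  on trees: random features identify nodes, a held-out node's neighbors are
  memorized training nodes, and neighbors share the branch label by
  construction, so graph structure alone carries the label.  The package's
  own no-signal null therefore permutes the *labels* (severing both the
  feature and the structure channel), and under that null accuracy does sit
  at the majority rate (see the unit suite).  The random-feature null is
  still computed and reported for transparency.
- The adaptive variants re-run the GAT (or k-hop pooling per distinct
  tagged node) on every training step; this is intended for small graphs —
  at full ontology scale the fixed-lookup variant is the practical default.
- The numpy engine is single-threaded-ish and float64; it is sized for
  desk-scale experiments, not for fine-tuning full-size encoders.
- Strict scores at the synthetic benchmark scale (tens of documents, tiny
  encoder) are far below what full-size pretrained encoders reach on real
  corpora; only the *difference* between matched models is meaningful here.
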