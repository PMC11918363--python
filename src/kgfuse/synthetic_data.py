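"""Synthetic ontologies and annotated ADE corpora.

The generator emulates the statistical structure the fusion model exploits
in real pharmacovigilance corpora: tree-shaped drug and symptom ontologies
whose classes carry labels and synonyms, and patient-report-style documents
in which ADE spans co-occur with lexicon entities at a controlled rate.
With probability ``p_signal`` an ADE span's surface form is a
symptom-lexicon phrase appearing in the same sentence as a drug mention (so
the rule-based tagger fires on it); otherwise the span is an out-of-lexicon
phrase.  Sentences may also contain distractor symptom mentions with no
drug nearby, which are *not* ADEs — the label depends on lexicon membership
plus the local drug cue, not on lexicon membership alone.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Annotation, Document
from .entity_tagger import build_lexicon, merge_lexicons
from .ontology import OntologyClass, OntologyGraph

__all__ = ["OntologySpec", "CorpusSpec", "make_word_list",
           "generate_ontology", "generate_corpus", "make_fusion_benchmark"]


class CapacityError(ValueError):
    """The vocabulary is too small for the requested ontology."""


def make_word_list(n: int, seed: int, min_len: int = 4,
                   max_len: int = 9) -> list[str]:
    """Pronounceable pseudo-words (CV syllables), unique, seeded."""
    rng = np.random.default_rng(seed)
    consonants = "bcdfghjklmnprstvwz"
    vowels = "aeiou"
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        length = int(rng.integers(min_len, max_len + 1))
        chars = []
        for i in range(length):
            pool = consonants if i % 2 == 0 else vowels
            chars.append(pool[int(rng.integers(len(pool)))])
        w = "".join(chars)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


@dataclass
class OntologySpec:
    n_classes: int = 200
    n_top: int = 14                  # branches directly under the root
    synonyms_per_class: int = 1
    vocab: list[str] = field(default_factory=list)
    seed: int = 0
    prefix: str = "SYN"
    max_phrase_words: int = 2

    def __post_init__(self):
        if not 0 < self.n_top < self.n_classes:
            raise ValueError("need 0 < n_top < n_classes")


def generate_ontology(spec: OntologySpec) -> OntologyGraph:
    """Random rooted tree ontology with annotated classes.

    The root has exactly ``n_top`` children; every other class attaches to
    a uniformly chosen non-root class.  Labels and synonyms are phrases of
    1..max_phrase_words words drawn without replacement from the vocabulary
    (so no two classes share a surface form).
    """
    rng = np.random.default_rng(spec.seed)
    vocab = list(spec.vocab) or make_word_list(
        spec.n_classes * (1 + spec.synonyms_per_class) * 2, spec.seed + 17)
    n_phrases = (spec.n_classes - 1) * (1 + spec.synonyms_per_class)
    if len(vocab) < n_phrases:  # every phrase needs at least one fresh word
        raise CapacityError(f"vocabulary of {len(vocab)} words cannot "
                            f"produce {n_phrases} unique phrases")
    pool = [vocab[i] for i in rng.permutation(len(vocab))]

    def draw_phrase() -> str:
        n_words = 1 + int(rng.random() < 0.35 and len(pool) > n_phrases)
        n_words = min(n_words, spec.max_phrase_words)
        return " ".join(pool.pop() for _ in range(n_words))

    ids = [f"{spec.prefix}:{i:07d}" for i in range(spec.n_classes)]
    root = ids[0]
    classes = {root: OntologyClass(id=root, label=f"{spec.prefix} root")}
    attachable: list[str] = []
    for i, cid in enumerate(ids[1:], 1):
        if i <= spec.n_top:
            parent = root
        else:
            parent = attachable[int(rng.integers(len(attachable)))]
        classes[cid] = OntologyClass(
            id=cid, label=draw_phrase(),
            synonyms=[draw_phrase() for _ in range(spec.synonyms_per_class)],
            definition="", parents=[parent])
        attachable.append(cid)
    return OntologyGraph(classes)


@dataclass
class CorpusSpec:
    n_docs: int = 100
    sentences_per_doc: float = 3.0     # Poisson mean (min 1)
    p_signal: float = 0.9              # ADE span is a symptom-lexicon phrase
    p_background_ade: float = 0.0      # extra out-of-lexicon ADE per sentence
    noise_rate: float = 0.05           # casing/typo perturbation per token
    p_ade_sentence: float = 0.6        # sentence carries an ADE event
    p_distractor: float = 0.3          # drug-free symptom mention (not ADE)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_signal, self.p_background_ade, self.noise_rate,
                  self.p_ade_sentence, self.p_distractor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_docs <= 0 or self.sentences_per_doc <= 0:
            raise ValueError("corpus size parameters must be positive")


def _surfaces(g: OntologyGraph, nodes: list[str] | None,
              rng: np.random.Generator) -> list[str]:
    chosen = nodes if nodes is not None else [n for n in g.nodes()
                                              if n != g.root]
    out = []
    for nid in chosen:
        cls = g.cls(nid)
        out.extend([s for s in [cls.label] + list(cls.synonyms) if s])
    return out


def generate_corpus(g_drug: OntologyGraph, g_symp: OntologyGraph,
                    spec: CorpusSpec,
                    symptom_nodes: list[str] | None = None,
                    filler_vocab: list[str] | None = None,
                    doc_prefix: str = "doc") -> list[Document]:
    """Annotated documents with gold ADE spans and drug/symptom provenance.

    Gold annotations carry types ``ADE`` (the NER target), plus ``Drug``
    and ``Symptom`` provenance records for inserted lexicon mentions.
    """
    rng = np.random.default_rng(spec.seed)
    drug_surfaces = _surfaces(g_drug, None, rng)
    symp_surfaces = _surfaces(g_symp, symptom_nodes, rng)
    if not drug_surfaces or (spec.p_signal > 0 and not symp_surfaces):
        raise ValueError("p_signal > 0 requires non-empty drug and symptom "
                         "lexicons")
    fillers = filler_vocab or make_word_list(2000, spec.seed + 29)
    # out-of-lexicon ADE phrases: fresh words never used elsewhere
    background_pool = make_word_list(400, spec.seed + 31, min_len=6)

    def pick(seq):
        return seq[int(rng.integers(len(seq)))]

    def filler_run(lo=2, hi=6):
        return [pick(fillers) for _ in range(int(rng.integers(lo, hi + 1)))]

    def noisy(tok: str) -> str:
        if rng.random() >= spec.noise_rate or len(tok) < 2:
            return tok
        if rng.random() < 0.5:
            return tok.capitalize()
        i = int(rng.integers(len(tok) - 1))
        return tok[:i] + tok[i + 1] + tok[i] + tok[i + 2:]

    docs: list[Document] = []
    for d in range(spec.n_docs):
        n_sents = max(1, int(rng.poisson(spec.sentences_per_doc)))
        tokens: list[str] = []
        # (tok_start, tok_end_exclusive, type) over the flat token list
        marks: list[tuple[int, int, str]] = []

        def add_words(words: list[str], kind: str | None = None,
                      noise_ok: bool = True):
            start = len(tokens)
            tokens.extend(noisy(w) if (noise_ok and kind is None) else w
                          for w in words)
            if kind:
                marks.append((start, len(tokens), kind))

        for _ in range(n_sents):
            add_words(filler_run())
            has_ade = rng.random() < spec.p_ade_sentence
            if has_ade and rng.random() < spec.p_signal:
                add_words(pick(drug_surfaces).split(), "Drug")
                add_words(filler_run(1, 3))
                start = len(tokens)
                add_words(pick(symp_surfaces).split(), "Symptom")
                marks.append((start, len(tokens), "ADE"))
            elif has_ade:
                add_words(pick(background_pool).split(), "ADE")
                add_words(filler_run(1, 3))
            elif rng.random() < spec.p_distractor:
                # symptom mention with no drug nearby: not an adverse event
                add_words(pick(symp_surfaces).split(), "Symptom")
            elif rng.random() < 0.5:
                add_words(pick(drug_surfaces).split(), "Drug")
            if rng.random() < spec.p_background_ade:
                add_words(filler_run(1, 2))
                add_words(pick(background_pool).split(), "ADE")
            add_words(filler_run(0, 3))
            add_words(["."], noise_ok=False)

        text_parts: list[str] = []
        char_at: list[int] = []
        pos = 0
        for t in tokens:
            char_at.append(pos)
            text_parts.append(t)
            pos += len(t) + 1
        text = " ".join(text_parts)
        anns = []
        for k, (ts, te, kind) in enumerate(sorted(marks)):
            cs, ce = char_at[ts], char_at[te - 1] + len(tokens[te - 1])
            anns.append(Annotation(id=f"T{k + 1}", type=kind,
                                   fragments=[(cs, ce)], text=text[cs:ce]))
        docs.append(Document.from_text(f"{doc_prefix}{d:04d}", text, anns))
    return docs


def benchmark_graphs(seed: int = 0, n_symptom_classes: int = 320,
                     n_drug_classes: int = 60,
                     ) -> tuple[OntologyGraph, OntologyGraph]:
    """The (drug, symptom) ontology pair used by the benchmark corpora."""
    g_symp = generate_ontology(OntologySpec(
        n_classes=n_symptom_classes, n_top=14, synonyms_per_class=0,
        seed=seed * 13 + 1, prefix="SYMP"))
    g_drug = generate_ontology(OntologySpec(
        n_classes=n_drug_classes, n_top=14, synonyms_per_class=1,
        seed=seed * 13 + 2, prefix="DRUG"))
    return g_drug, g_symp


def make_fusion_benchmark(seed: int = 0, overlap: float = 0.5,
                          n_symptom_classes: int = 320,
                          n_drug_classes: int = 60,
                          n_train_docs: int = 80, n_val_docs: int = 20,
                          n_test_docs: int = 40,
                          corpus_spec: CorpusSpec | None = None) -> dict:
    """Full study setup for the knowledge-advantage experiment.

    Builds drug and symptom ontologies, a combined knowledge graph and
    lexicon, and train/validation/test corpora whose symptom surface forms
    overlap between the training and test pools at the requested fraction
    (default 0.5), so a model without the lexicon cannot have memorized
    half of the test symptom vocabulary.
    """
    base = corpus_spec or CorpusSpec(p_signal=0.9)
    rng = np.random.default_rng(seed)
    g_drug, g_symp = benchmark_graphs(seed, n_symptom_classes,
                                      n_drug_classes)
    symp_nodes = [n for n in g_symp.nodes() if n != g_symp.root]
    symp_nodes = [symp_nodes[i] for i in rng.permutation(len(symp_nodes))]
    m = len(symp_nodes) // 2
    k = int(round(overlap * m))
    train_pool = symp_nodes[:m]
    test_pool = symp_nodes[m - k: 2 * m - k]

    def sp(n_docs: int, salt: int, **kw) -> CorpusSpec:
        return CorpusSpec(n_docs=n_docs,
                          sentences_per_doc=base.sentences_per_doc,
                          p_signal=base.p_signal,
                          p_background_ade=base.p_background_ade,
                          noise_rate=base.noise_rate,
                          p_ade_sentence=base.p_ade_sentence,
                          p_distractor=base.p_distractor,
                          seed=seed * 7 + salt, **kw)

    fillers = make_word_list(2000, seed * 7 + 5)
    train_docs = generate_corpus(g_drug, g_symp, sp(n_train_docs, 101),
                                 symptom_nodes=train_pool,
                                 filler_vocab=fillers, doc_prefix="train")
    val_docs = generate_corpus(g_drug, g_symp, sp(n_val_docs, 102),
                               symptom_nodes=train_pool,
                               filler_vocab=fillers, doc_prefix="val")
    test_docs = generate_corpus(g_drug, g_symp, sp(n_test_docs, 103),
                                symptom_nodes=test_pool,
                                filler_vocab=fillers, doc_prefix="test")
    lexicon = merge_lexicons(build_lexicon(g_drug, "drug"),
                             build_lexicon(g_symp, "symptom"))
    return {"g_drug": g_drug, "g_symp": g_symp, "lexicon": lexicon,
            "train_docs": train_docs, "val_docs": val_docs,
            "test_docs": test_docs, "train_pool": train_pool,
            "test_pool": test_pool}
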