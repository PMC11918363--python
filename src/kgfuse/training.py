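"""Experimental protocol: splits, NER training, hyperparameter search.

The protocol reserves 20% of the documents as an untouched test set, splits
the remainder 4-to-1 into train and validation (64/16/20 overall), tunes
hyperparameters by sequential model-based search maximizing validation
strict F1, then retrains the final model from scratch on train+validation
before the single test evaluation.  Splitting is at document level so
sentences of one post/report never straddle partitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._tensor import masked_cross_entropy
from .corpus_io import Document, gold_iob_labels
from .encoder import EncodedInput, TinyTransformerEncoder, WordPieceTokenizer
from .entity_tagger import Lexicon, TaggedSequence
from .evaluation import Span, iob_to_spans, strict_prf
from .fusion_ner import FusionNERModel, VariantConfig
from .nn import AdamW

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "Hyperparameters", "split_dataset", "train_ner",
           "tune_hyperparameters", "final_fit", "FusionNERTagger",
           "LeakageError", "SentenceExample"]


class LeakageError(ValueError):
    """A test document appears in the training material."""


@dataclass
class SplitSpec:
    test_frac: float = 0.20
    val_frac_of_rest: float = 0.20   # 4-to-1 train/validation
    seed: int = 0


@dataclass
class Hyperparameters:
    learning_rate: float = 3e-4
    batch_size: int = 16
    epochs: int = 5
    weight_decay: float = 0.01
    head_dropout: float = 0.1
    warmup_frac: float = 0.1

    def __post_init__(self):
        if self.learning_rate < 0 or self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("invalid hyperparameters")
        if not (0 <= self.warmup_frac <= 1 and 0 <= self.head_dropout < 1):
            raise ValueError("invalid hyperparameters")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(corpus: list[Document], spec: SplitSpec | None = None,
                  ) -> tuple[list[Document], list[Document], list[Document]]:
    """Document-level random partition into train/validation/test.

    |test| = round(test_frac * n), |val| = round(val_frac_of_rest * rest);
    round-half-up, deterministic for a fixed seed.
    """
    spec = spec or SplitSpec()
    n = len(corpus)
    if n < 5:
        raise ValueError(f"need at least 5 documents, got {n}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_test = _round_half_up(spec.test_frac * n)
    n_val = _round_half_up(spec.val_frac_of_rest * (n - n_test))
    test = [corpus[i] for i in order[:n_test]]
    val = [corpus[i] for i in order[n_test:n_test + n_val]]
    train = [corpus[i] for i in order[n_test + n_val:]]
    return train, val, test


# ------------------------------------------------------------ example prep

@dataclass
class SentenceExample:
    """One sentence ready for the model: words, gold IOB, encoding, tags."""

    doc_id: str
    sent_idx: int
    words: list[str]
    gold: list[str]
    enc: EncodedInput = None
    tagged: TaggedSequence = None


def make_examples(docs: list[Document]) -> list[SentenceExample]:
    examples = []
    for doc in docs:
        labels = gold_iob_labels(doc)
        for si, (words, labs) in enumerate(zip(doc.sentences, labels)):
            if words:
                examples.append(SentenceExample(doc.id, si, words, labs))
    return examples


def _prepare(examples: list[SentenceExample], model: FusionNERModel) -> None:
    for ex in examples:
        if ex.enc is None:
            ex.enc = model.tokenizer.encode_words(
                ex.words, max_len=model.encoder.max_len)
            ex.tagged = model.tag_words(ex.words)


def _loss_arrays(batch: list[SentenceExample], L: int):
    """Per-piece integer labels and a loss mask selecting pivotal pieces."""
    name_to_id = {"O": 0, "B": 1, "I": 2}
    labels = np.zeros((len(batch), L), dtype=np.int64)
    mask = np.zeros((len(batch), L), dtype=np.float64)
    for i, ex in enumerate(batch):
        for w, lab in enumerate(ex.gold):
            lo, hi = ex.enc.word_to_pieces[w]
            if hi > lo:  # subword policy: label on first piece, rest ignored
                labels[i, lo] = name_to_id[lab]
                mask[i, lo] = 1.0
    return labels, mask


def predict_spans(model: FusionNERModel, examples: list[SentenceExample],
                  batch_size: int = 32) -> tuple[set[Span], set[Span]]:
    """(gold, predicted) span sets over a list of sentence examples."""
    _prepare(examples, model)
    gold: set[Span] = set()
    pred: set[Span] = set()
    for ex in examples:
        gold |= iob_to_spans(ex.gold, doc=ex.doc_id, sent=ex.sent_idx)
    for i in range(0, len(examples), batch_size):
        chunk = examples[i:i + batch_size]
        labels = model.predict_labels([ex.enc for ex in chunk],
                                      [ex.tagged for ex in chunk],
                                      [len(ex.words) for ex in chunk])
        for ex, labs in zip(chunk, labels):
            pred |= iob_to_spans(labs, doc=ex.doc_id, sent=ex.sent_idx)
    return gold, pred


# ------------------------------------------------------------ training loop

def train_ner(model: FusionNERModel, train: list[SentenceExample],
              val: list[SentenceExample], hp: Hyperparameters, seed: int = 0,
              ) -> tuple[FusionNERModel, dict]:
    """Token-level cross-entropy training with AdamW.

    Masked (non-pivotal) subword positions are ignored by the loss; the
    checkpoint with the best validation strict F1 is restored at the end.
    History records per-epoch mean train loss and validation F1.
    """
    if not train:
        raise ValueError("empty training set")
    _prepare(train, model)
    _prepare(val, model)
    model.head_dropout = hp.head_dropout
    opt = AdamW(model.parameters(), lr=hp.learning_rate,
                weight_decay=hp.weight_decay)
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 1)
    total_steps = max(1, hp.epochs * math.ceil(len(train) / hp.batch_size))
    warmup_steps = int(hp.warmup_frac * total_steps)
    history = {"train_loss": [], "val_f1": []}
    best = (-1.0, None)
    step = 0
    for _ in range(hp.epochs):
        order = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(train), hp.batch_size):
            batch = [train[i] for i in order[lo:lo + hp.batch_size]]
            encs = [ex.enc for ex in batch]
            tagged = [ex.tagged for ex in batch]
            opt.zero_grad()
            logits = model.forward(encs, tagged, drop_rng)
            labels, mask = _loss_arrays(batch, logits.shape[1])
            loss = masked_cross_entropy(logits, labels, mask)
            loss.backward()
            step += 1
            opt.lr = hp.learning_rate * (
                step / warmup_steps if warmup_steps and step < warmup_steps
                else 1.0)
            if hp.learning_rate > 0:
                opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val:
            gold, pred = predict_spans(model, val)
            f1 = strict_prf(gold, pred).f1
        else:
            f1 = float("nan")
        history["val_f1"].append(f1)
        if val and f1 > best[0]:
            best = (f1, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    history["final_train_loss"] = (history["train_loss"][-1]
                                   if history["train_loss"] else float("nan"))
    return model, history


# --------------------------------------------------- TPE-style tuner

def _sample_param(spec, rng: np.random.Generator):
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "log_uniform":
        return float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
    if kind == "int":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "categorical":
        return spec[1][int(rng.integers(len(spec[1])))]
    raise ValueError(f"invalid search-space entry {spec!r}")


def _kde_logpdf(x: float, obs: list[float], lo: float, hi: float,
                log_scale: bool) -> float:
    if log_scale:
        x, obs = np.log(x), np.log(np.asarray(obs, dtype=float))
        lo, hi = np.log(lo), np.log(hi)
    else:
        obs = np.asarray(obs, dtype=float)
    bw = max((hi - lo) / max(len(obs), 1), 1e-6)
    dens = np.exp(-0.5 * ((x - obs) / bw) ** 2).sum() / (len(obs) * bw)
    return float(np.log(dens + 1e-12))


def tune_hyperparameters(space: dict, budget: int, objective,
                         seed: int = 0, gamma: float = 0.25,
                         n_candidates: int = 24,
                         ) -> tuple[dict, list[dict]]:
    """Sequential model-based (TPE-style) maximization of the objective.

    The first trials are random; afterwards each parameter is sampled from
    a kernel-density model of the top ``gamma`` fraction of trials and the
    candidate maximizing the good/bad density ratio is chosen.  Returns the
    best parameter dict and the full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    for name, spec in space.items():
        if spec[0] in ("uniform", "log_uniform", "int") and spec[1] > spec[2]:
            raise ValueError(f"invalid bounds for {name!r}")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    n_startup = min(budget, max(3, budget // 4))
    for t in range(budget):
        if t < n_startup:
            params = {k: _sample_param(v, rng) for k, v in space.items()}
        else:
            ranked = sorted(trials, key=lambda tr: -tr["objective"])
            n_good = max(1, int(np.ceil(gamma * len(ranked))))
            good, bad = ranked[:n_good], ranked[n_good:] or ranked[:1]
            params = {}
            for k, spec in space.items():
                if spec[0] == "categorical":
                    weights = np.ones(len(spec[1]))
                    for tr in good:
                        weights[spec[1].index(tr["params"][k])] += 1.0
                    params[k] = spec[1][int(rng.choice(len(spec[1]),
                                            p=weights / weights.sum()))]
                    continue
                log_scale = spec[0] == "log_uniform"
                cands = [_sample_param(spec, rng) for _ in range(n_candidates)]
                g_obs = [tr["params"][k] for tr in good]
                b_obs = [tr["params"][k] for tr in bad]
                scores = [_kde_logpdf(c, g_obs, spec[1], spec[2], log_scale)
                          - _kde_logpdf(c, b_obs, spec[1], spec[2], log_scale)
                          for c in cands]
                best_c = cands[int(np.argmax(scores))]
                params[k] = int(round(best_c)) if spec[0] == "int" else best_c
        value = float(objective(params))
        trials.append({"trial": t, "params": params, "objective": value})
        logger.info("trial %d: objective=%.4f params=%s", t, value, params)
    best = max(trials, key=lambda tr: (tr["objective"], -tr["trial"]))
    return dict(best["params"]), trials


DEFAULT_SEARCH_SPACE = {
    "learning_rate": ("log_uniform", 1e-5, 1e-4),
    "batch_size": ("categorical", [8, 16, 32]),
    "epochs": ("int", 2, 10),
    "weight_decay": ("uniform", 0.0, 0.1),
    "head_dropout": ("uniform", 0.0, 0.3),
}


# ------------------------------------------------------------- final refit

def final_fit(model_factory, train: list[SentenceExample],
              val: list[SentenceExample], best_hp: Hyperparameters,
              seed: int = 0, test: list[SentenceExample] | None = None,
              ) -> FusionNERModel:
    """Retrain from scratch on train+validation with the tuned settings.

    Guards against leakage: no document of the test set may appear in the
    combined training material.
    """
    if test:
        test_ids = {ex.doc_id for ex in test}
        leaked = {ex.doc_id for ex in train + val} & test_ids
        if leaked:
            raise LeakageError(f"test documents in training data: "
                               f"{sorted(leaked)[:5]}")
    model = model_factory()
    if best_hp.epochs == 0:
        return model
    combined = train + val
    model, _ = train_ner(model, combined, [], best_hp, seed=seed)
    return model


# -------------------------------------------------------------- estimator

class FusionNERTagger(BaseEstimator):
    """Scikit-learn style ADE span tagger with optional knowledge fusion.

    ``variant`` selects the architecture: "baseline" (knowledge-free),
    "fixed", "adaptive" or "adaptive_subgraph".  Knowledge resources
    (lexicon, embedding table / graph + GAT + features) are constructor
    parameters; the wordpiece tokenizer is trained on the fit documents
    when not supplied.

    Attributes after ``fit``: ``model_`` (the trained network),
    ``history_`` (per-epoch train loss and validation strict F1),
    ``tokenizer_``.
    """

    def __init__(self, variant: str = "baseline", k: int | None = None,
                 lexicon: Lexicon | None = None, embedding_table=None,
                 graph=None, gat=None, feats=None,
                 tokenizer: WordPieceTokenizer | None = None,
                 hidden_size: int = 32, n_layers: int = 2, n_heads: int = 2,
                 ffn_dim: int = 64, max_len: int = 64, vocab_size: int = 800,
                 learning_rate: float = 2e-3, batch_size: int = 16,
                 epochs: int = 8, weight_decay: float = 0.01,
                 head_dropout: float = 0.1, warmup_frac: float = 0.1,
                 seed: int = 0):
        self.variant = variant
        self.k = k
        self.lexicon = lexicon
        self.embedding_table = embedding_table
        self.graph = graph
        self.gat = gat
        self.feats = feats
        self.tokenizer = tokenizer
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.max_len = max_len
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.head_dropout = head_dropout
        self.warmup_frac = warmup_frac
        self.seed = seed

    def _hp(self) -> Hyperparameters:
        return Hyperparameters(learning_rate=self.learning_rate,
                               batch_size=self.batch_size, epochs=self.epochs,
                               weight_decay=self.weight_decay,
                               head_dropout=self.head_dropout,
                               warmup_frac=self.warmup_frac)

    def build_model(self) -> FusionNERModel:
        encoder = TinyTransformerEncoder(
            vocab_size=self.tokenizer_.vocab_size,
            hidden_size=self.hidden_size, n_layers=self.n_layers,
            n_heads=self.n_heads, ffn_dim=self.ffn_dim, max_len=self.max_len,
            seed=self.seed)
        if self.variant == "baseline":
            return FusionNERModel(encoder, self.tokenizer_,
                                  head_dropout=self.head_dropout,
                                  seed=self.seed)
        cfg = VariantConfig(variant=self.variant, k=self.k)
        return FusionNERModel(encoder, self.tokenizer_, lexicon=self.lexicon,
                              cfg=cfg, embedding_table=self.embedding_table,
                              graph=self.graph, gat=self.gat,
                              feats=self.feats,
                              head_dropout=self.head_dropout, seed=self.seed)

    def fit(self, docs: list[Document], val_docs: list[Document] | None = None,
            ) -> "FusionNERTagger":
        if self.tokenizer is not None:
            self.tokenizer_ = self.tokenizer
        else:
            self.tokenizer_ = WordPieceTokenizer.train(
                [d.text for d in docs], vocab_size=self.vocab_size)
        self.model_ = self.build_model()
        train = make_examples(docs)
        val = make_examples(val_docs) if val_docs else []
        self.model_, self.history_ = train_ner(self.model_, train, val,
                                               self._hp(), seed=self.seed)
        return self

    def predict(self, docs: list[Document]) -> set[Span]:
        if not hasattr(self, "model_"):
            raise ValueError("estimator is not fitted")
        examples = make_examples(docs)
        _, pred = predict_spans(self.model_, examples)
        return pred

    def score(self, docs: list[Document]) -> float:
        """Strict span F1 (in percent) on gold-annotated documents."""
        examples = make_examples(docs)
        gold, pred = predict_spans(self.model_, examples)
        return strict_prf(gold, pred).f1
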