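"""Protocol: splits, training loop, hyperparameter search, final refit."""

import numpy as np
import pytest

from kgfuse.corpus_io import Document
from kgfuse.synthetic_data import (CorpusSpec, OntologySpec, generate_corpus,
                                   generate_ontology)
from kgfuse.training import (FusionNERTagger, Hyperparameters, LeakageError,
                             SplitSpec, final_fit, make_examples,
                             split_dataset, train_ner, tune_hyperparameters)


def docs(n):
    return [Document.from_text(f"d{i}", f"text number {i}.")
            for i in range(n)]


def test_split_100_gives_64_16_20():
    train, val, test = split_dataset(docs(100), SplitSpec(seed=0))
    assert (len(train), len(val), len(test)) == (64, 16, 20)


def test_split_7_rounds_half_up():
    train, val, test = split_dataset(docs(7), SplitSpec(seed=1))
    # round(0.2*7)=1 test; round(0.2*6)=1 val; 5 train
    assert (len(train), len(val), len(test)) == (5, 1, 1)


def test_split_partitions_and_is_deterministic():
    corpus = docs(53)
    a = split_dataset(corpus, SplitSpec(seed=3))
    b = split_dataset(corpus, SplitSpec(seed=3))
    ids = [sorted(d.id for d in part) for part in a]
    assert ids == [sorted(d.id for d in part) for part in b]
    flat = [d.id for part in a for d in part]
    assert sorted(flat) == sorted(d.id for d in corpus)
    assert len(set(flat)) == len(flat)
    assert split_dataset(corpus, SplitSpec(seed=4))[2][0].id != a[2][0].id \
        or True  # different seed may coincide on tiny sets; no assertion


def test_split_needs_five_documents():
    with pytest.raises(ValueError):
        split_dataset(docs(4))


@pytest.fixture(scope="module")
def tiny_corpus():
    g_symp = generate_ontology(OntologySpec(n_classes=60, n_top=4, seed=1,
                                            prefix="SYMP"))
    g_drug = generate_ontology(OntologySpec(n_classes=20, n_top=4, seed=2,
                                            prefix="DRUG"))
    corpus = generate_corpus(g_drug, g_symp,
                             CorpusSpec(n_docs=24, seed=3, p_signal=1.0))
    return split_dataset(corpus, SplitSpec(seed=0))


def test_training_reduces_loss_and_is_reproducible(tiny_corpus):
    train_docs, val_docs, _ = tiny_corpus
    histories = []
    for _ in range(2):
        est = FusionNERTagger(variant="baseline", epochs=5, batch_size=8,
                              hidden_size=16, seed=11)
        est.fit(train_docs, val_docs)
        histories.append(est.history_)
    h = histories[0]
    assert h["train_loss"][-1] < h["train_loss"][0]
    assert histories[0] == histories[1]  # fixed seed: identical history


def test_zero_learning_rate_changes_nothing(tiny_corpus):
    train_docs, val_docs, _ = tiny_corpus
    est = FusionNERTagger(variant="baseline", epochs=3, learning_rate=0.0,
                          head_dropout=0.0, hidden_size=16, seed=5)
    est.tokenizer_ = est.tokenizer or __import__(
        "kgfuse.encoder", fromlist=["WordPieceTokenizer"]
    ).WordPieceTokenizer.train([d.text for d in train_docs], vocab_size=300)
    model = est.build_model()
    before = {k: v.copy() for k, v in model.state_dict().items()}
    model, history = train_ner(model, make_examples(train_docs),
                               make_examples(val_docs), est._hp(), seed=5)
    # weights untouched and the validation F1 is flat across epochs
    assert len(set(history["val_f1"])) == 1
    after = model.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_empty_training_set_rejected(tiny_corpus):
    train_docs, _, _ = tiny_corpus
    est = FusionNERTagger(hidden_size=16, seed=0)
    with pytest.raises(ValueError, match="empty"):
        est.fit([])


def test_tune_budget_one_and_argmax_contract():
    space = {"x": ("uniform", 0.0, 1.0), "n": ("int", 1, 4),
             "c": ("categorical", ["a", "b"])}

    def objective(params):
        return -(params["x"] - 0.3) ** 2 + params["n"] * 0.01

    best1, log1 = tune_hyperparameters(space, 1, objective, seed=0)
    assert len(log1) == 1 and best1 == log1[0]["params"]
    best, log = tune_hyperparameters(space, 12, objective, seed=0)
    best_logged = max(t["objective"] for t in log)
    chosen = [t for t in log if t["params"] == best][0]
    assert chosen["objective"] == best_logged


def test_tune_is_deterministic_per_seed():
    space = {"x": ("log_uniform", 1e-4, 1e-1)}
    obj = lambda p: -abs(np.log10(p["x"]) + 2.5)
    a = tune_hyperparameters(space, 6, obj, seed=7)
    b = tune_hyperparameters(space, 6, obj, seed=7)
    assert a == b


def test_tune_rejects_bad_bounds():
    with pytest.raises(ValueError):
        tune_hyperparameters({"x": ("uniform", 2.0, 1.0)}, 2, lambda p: 0.0)


def test_final_fit_guards_leakage_and_epochs_zero(tiny_corpus):
    train_docs, val_docs, test_docs = tiny_corpus
    train_ex = make_examples(train_docs)
    val_ex = make_examples(val_docs)
    test_ex = make_examples(test_docs)
    est = FusionNERTagger(variant="baseline", hidden_size=16, seed=0)
    est.tokenizer_ = __import__(
        "kgfuse.encoder", fromlist=["WordPieceTokenizer"]
    ).WordPieceTokenizer.train([d.text for d in train_docs], vocab_size=300)

    with pytest.raises(LeakageError):
        final_fit(est.build_model, train_ex + test_ex[:1], val_ex,
                  Hyperparameters(epochs=1), test=test_ex)

    model = final_fit(est.build_model, train_ex, val_ex,
                      Hyperparameters(epochs=0), test=test_ex)
    fresh = est.build_model()
    a, b = model.state_dict(), fresh.state_dict()
    assert all(np.array_equal(a[k], b[k]) for k in a)

    ids = {ex.doc_id for ex in train_ex} | {ex.doc_id for ex in val_ex}
    assert len(ids) == len(train_docs) + len(val_docs)


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        Hyperparameters(learning_rate=-1.0)
    with pytest.raises(ValueError):
        Hyperparameters(warmup_frac=2.0)
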