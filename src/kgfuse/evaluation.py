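"""Span-level evaluation and corpus characterization.

Per-token IOB predictions are aggregated into ADE mention spans, and
precision/recall/F1 are computed at the span level: *strict* scoring
credits a prediction only when its full extent exactly matches a gold span,
*relaxed* scoring requires at least one token of overlap.  Scores are
micro-averaged over all spans by default (a macro flag averages per
document).  Corpus characterization reports mean wordpiece diversity, mean
sentence length in wordpieces, and mean knowledge-graph hits per sentence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .entity_tagger import Lexicon, tag

__all__ = ["Span", "EvalReport", "CorpusStats", "iob_to_spans",
           "strict_prf", "relaxed_prf", "corpus_stats"]


@dataclass(frozen=True, order=True)
class Span:
    """An ADE mention located by document, sentence, and token range."""

    doc: str
    sent: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("span start after end")


@dataclass
class EvalReport:
    precision: float     # percentages in [0, 100]
    recall: float
    f1: float
    mode: str            # strict | relaxed
    tp: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "mode": self.mode,
                "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn}}


@dataclass
class CorpusStats:
    mean_wordpiece_diversity: float
    mean_sentence_length: float
    mean_kg_hits: float


def iob_to_spans(labels: list[str], doc: str = "", sent: int = 0,
                 ) -> set[Span]:
    """Aggregate an IOB sequence into mention spans.

    Each maximal ``B I*`` run becomes one span.  An ``I`` with no live span
    (sequence-initial or following ``O``) opens a new span — the standard
    conlleval-style repair, which affects counts only on malformed input.
    """
    spans: set[Span] = set()
    start = None
    for i, lab in enumerate(labels):
        if lab not in ("O", "B", "I"):
            raise ValueError(f"invalid IOB label {lab!r} at position {i}")
        if lab == "B" or (lab == "I" and start is None):
            if start is not None:
                spans.add(Span(doc, sent, start, i - 1))
            start = i
        elif lab == "O":
            if start is not None:
                spans.add(Span(doc, sent, start, i - 1))
            start = None
    if start is not None:
        spans.add(Span(doc, sent, start, len(labels) - 1))
    return spans


def _report(tp: int, fp: int, fn: int, mode: str) -> EvalReport:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EvalReport(precision=p, recall=r, f1=f1, mode=mode,
                      tp=tp, fp=fp, fn=fn)


def strict_prf(gold: set[Span], pred: set[Span]) -> EvalReport:
    """Exact-extent span matching, micro-averaged.

    TP is the number of predicted spans identical (document, sentence,
    start, end) to a gold span; empty denominators score 0.
    """
    tp = len(gold & pred)
    return _report(tp, len(pred) - tp, len(gold) - tp, "strict")


def relaxed_prf(gold: set[Span], pred: set[Span]) -> EvalReport:
    """Partial-overlap span matching with one-to-one greedy credit.

    A predicted span may match any same-sentence gold span it overlaps in
    at least one token; pairs are matched greedily by overlap size then by
    left position, so each gold span is credited at most once and duplicate
    predictions cannot double-count.
    """
    candidates = []
    for p in pred:
        for g in gold:
            if p.doc == g.doc and p.sent == g.sent \
                    and p.start <= g.end and g.start <= p.end:
                overlap = min(p.end, g.end) - max(p.start, g.start) + 1
                candidates.append((-overlap, p.start, g.start, p, g))
    candidates.sort(key=lambda c: (c[0], c[1], c[2],
                                   (c[3].doc, c[3].sent, c[3].start, c[3].end),
                                   (c[4].doc, c[4].sent, c[4].start, c[4].end)))
    used_pred: set[Span] = set()
    used_gold: set[Span] = set()
    tp = 0
    for _, _, _, p, g in candidates:
        if p in used_pred or g in used_gold:
            continue
        used_pred.add(p)
        used_gold.add(g)
        tp += 1
    return _report(tp, len(pred) - tp, len(gold) - tp, "relaxed")


def macro_prf(per_doc: list[tuple[set[Span], set[Span]]],
              mode: str = "strict") -> EvalReport:
    """Macro average of per-document scores (exposed for comparability)."""
    fn = strict_prf if mode == "strict" else relaxed_prf
    reports = [fn(g, p) for g, p in per_doc]
    if not reports:
        raise ValueError("no documents to evaluate")
    p = sum(r.precision for r in reports) / len(reports)
    r_ = sum(r.recall for r in reports) / len(reports)
    f1 = 2 * p * r_ / (p + r_) if p + r_ else 0.0
    return EvalReport(precision=p, recall=r_, f1=f1, mode=f"macro-{mode}",
                      tp=sum(r.tp for r in reports),
                      fp=sum(r.fp for r in reports),
                      fn=sum(r.fn for r in reports))


def corpus_stats(documents, tokenizer, lexicon: Lexicon) -> CorpusStats:
    """Per-sentence statistics averaged over all sentences of a corpus.

    diversity = unique wordpieces / total wordpieces; length = wordpiece
    count; a KG hit is a lexicon-tagged entity mention in the sentence.
    """
    diversities, lengths, hits = [], [], []
    for doc in documents:
        for tokens in doc.sentences:
            if not tokens:
                continue
            pieces = [p for w in tokens for p in tokenizer.tokenize_word(w)]
            if not pieces:
                continue
            diversities.append(len(set(pieces)) / len(pieces))
            lengths.append(len(pieces))
            hits.append(len(tag(tokens, lexicon).spans) if lexicon.entries
                        else 0)
    if not lengths:
        raise ValueError("corpus has no sentences")
    n = len(lengths)
    return CorpusStats(mean_wordpiece_diversity=sum(diversities) / n,
                       mean_sentence_length=sum(lengths) / n,
                       mean_kg_hits=sum(hits) / n)
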