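"""Readers and writers for annotated ADE corpora.

Three interchange formats are supported, matching how public ADE corpora
are distributed: brat standoff (.txt + .ann with character offsets,
CADEC-style), CoNLL-style IOB (token TAB label, blank line between
sentences), and JSONL (one document per line with character-offset spans).
Character-offset annotations are projected onto token spans for training;
only the ADE annotation type is used as the NER target, other gold types
are carried through untouched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .encoder import sentence_split, word_tokenize

logger = logging.getLogger(__name__)

__all__ = ["Annotation", "Document", "read_brat", "read_conll_iob",
           "write_conll_iob", "read_jsonl", "write_jsonl",
           "project_char_spans", "gold_token_spans", "gold_iob_labels",
           "IntegrityError", "CorpusFormatError"]

TARGET_TYPE = "ADE"
IOB_LABELS = ("O", "B", "I")


class IntegrityError(ValueError):
    """Annotation surface text disagrees with its character offsets."""


class CorpusFormatError(ValueError):
    """Malformed corpus file."""


@dataclass
class Annotation:
    """A character-offset annotation; discontinuous ones carry several
    fragments under one id."""

    id: str
    type: str
    fragments: list[tuple[int, int]]
    text: str

    @property
    def start(self) -> int:
        return min(s for s, _ in self.fragments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.fragments)


@dataclass
class Document:
    id: str
    text: str
    sentences: list[list[str]]                       # tokens per sentence
    token_offsets: list[list[tuple[int, int]]]       # char ranges per token
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        for ann in self.annotations:
            for s, e in ann.fragments:
                if not (0 <= s < e <= len(self.text)):
                    raise IntegrityError(
                        f"{self.id}/{ann.id}: offsets {s}-{e} outside text")

    @classmethod
    def from_text(cls, doc_id: str, text: str,
                  annotations: list[Annotation] | None = None) -> "Document":
        sentences, offsets = [], []
        for s, e in sentence_split(text):
            toks = word_tokenize(text[s:e])
            sentences.append([t for t, _, _ in toks])
            offsets.append([(s + a, s + b) for _, a, b in toks])
        if not sentences and text.strip():
            toks = word_tokenize(text)
            sentences = [[t for t, _, _ in toks]]
            offsets = [[(a, b) for _, a, b in toks]]
        return cls(id=doc_id, text=text, sentences=sentences,
                   token_offsets=offsets, annotations=annotations or [])


# ------------------------------------------------------------ brat standoff

def read_brat(txt_path: str | Path, ann_path: str | Path) -> Document:
    """Parse a brat .txt/.ann pair; verifies surfaces against offsets."""
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text()
    annotations: list[Annotation] = []
    for lineno, line in enumerate(ann_path.read_text().splitlines(), 1):
        if not line.strip() or not line.startswith("T"):
            continue  # only entity (T) lines carry spans
        try:
            ann_id, middle, surface = line.split("\t", 2)
            head, *rest = middle.split(" ", 1)
            fragments = [tuple(int(x) for x in frag.split())
                         for frag in rest[0].split(";")]
        except (ValueError, IndexError) as exc:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: malformed T-line") from exc
        joined = " ".join(text[s:e] for s, e in fragments)
        if joined != surface:
            raise IntegrityError(
                f"{ann_path}:{lineno}: annotation {ann_id} text "
                f"{surface!r} does not match offsets ({joined!r})")
        annotations.append(Annotation(id=ann_id, type=head,
                                      fragments=[(int(s), int(e))
                                                 for s, e in fragments],
                                      text=surface))
    return Document.from_text(txt_path.stem, text, annotations)


def write_brat(doc: Document, txt_path: str | Path,
               ann_path: str | Path) -> None:
    Path(txt_path).write_text(doc.text)
    with open(ann_path, "w") as fh:
        for ann in doc.annotations:
            frags = ";".join(f"{s} {e}" for s, e in ann.fragments)
            fh.write(f"{ann.id}\t{ann.type} {frags}\t{ann.text}\n")


# --------------------------------------------------------------- CoNLL IOB

def read_conll_iob(path: str | Path) -> list[tuple["Document", list[list[str]]]]:
    """Read CoNLL-style IOB: returns (document, per-sentence labels) pairs.

    Lines are ``token TAB label``; a blank line separates sentences and a
    ``# doc_id = NAME`` comment starts a new document.  CRLF input is
    accepted and normalized.
    """
    path = Path(path)
    raw = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    if not raw.strip():
        logger.warning("empty CoNLL file %s", path)
        return []
    docs: list[tuple[Document, list[list[str]]]] = []
    cur_id = path.stem
    sentences: list[list[str]] = []
    labels: list[list[str]] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush_sentence():
        if tokens:
            sentences.append(list(tokens))
            labels.append(list(tags))
            tokens.clear()
            tags.clear()

    def flush_doc():
        flush_sentence()
        if sentences:
            docs.append((_doc_from_tokens(cur_id, list(sentences)),
                         list(labels)))
            sentences.clear()
            labels.clear()

    for lineno, line in enumerate(raw.split("\n"), 1):
        if line.startswith("# doc_id ="):
            flush_doc()
            cur_id = line.split("=", 1)[1].strip()
            continue
        if not line.strip():
            flush_sentence()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusFormatError(f"{path}:{lineno}: expected "
                                    f"'token TAB label', got {line!r}")
        tok, lab = parts
        base = lab.split("-", 1)[0]
        if base not in IOB_LABELS:
            raise CorpusFormatError(f"{path}:{lineno}: unknown label {lab!r}")
        tokens.append(tok)
        tags.append(lab)
    flush_doc()
    return docs


def _doc_from_tokens(doc_id: str, sentences: list[list[str]]) -> Document:
    """Build a Document whose text is the space-joined tokens."""
    parts, offsets = [], []
    pos = 0
    for sent in sentences:
        sent_offsets = []
        for tok in sent:
            sent_offsets.append((pos, pos + len(tok)))
            parts.append(tok)
            pos += len(tok) + 1
        offsets.append(sent_offsets)
    return Document(id=doc_id, text=" ".join(parts), sentences=sentences,
                    token_offsets=offsets)


def write_conll_iob(docs: list[tuple[Document, list[list[str]]]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for doc, labels in docs:
            fh.write(f"# doc_id = {doc.id}\n")
            for sent, labs in zip(doc.sentences, labels):
                for tok, lab in zip(sent, labs):
                    fh.write(f"{tok}\t{lab}\n")
                fh.write("\n")


# ------------------------------------------------------------------- JSONL

def read_jsonl(path: str | Path) -> list[Document]:
    docs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: bad JSON") from exc
            anns = [Annotation(id=f"T{i + 1}", type=sp["type"],
                               fragments=[(sp["start"], sp["end"])],
                               text=sp.get("text",
                                           rec["text"][sp["start"]:sp["end"]]))
                    for i, sp in enumerate(rec.get("spans", []))]
            for ann in anns:
                s, e = ann.fragments[0]
                if rec["text"][s:e] != ann.text:
                    raise IntegrityError(
                        f"{path}:{lineno}: span text mismatch for {ann.id}")
            docs.append(Document.from_text(rec["id"], rec["text"], anns))
    return docs


def write_jsonl(docs: list[Document], path: str | Path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            spans = [{"start": a.start, "end": a.end, "type": a.type,
                      "text": doc.text[a.start:a.end]}
                     for a in doc.annotations]
            fh.write(json.dumps({"id": doc.id, "text": doc.text,
                                 "spans": spans}) + "\n")


# ------------------------------------------------- char -> token projection

def project_char_spans(doc: Document, char_start: int, char_end: int,
                       ) -> list[tuple[int, int, int]]:
    """Map a character range to minimal covering token spans.

    Returns (sentence_index, token_start, token_end) triples, inclusive
    token indices; a range crossing sentence boundaries yields one triple
    per sentence; partial token overlap rounds outward to the whole token.
    """
    if char_end <= char_start:
        raise ValueError("zero-length or inverted character span")
    if char_start < 0 or char_end > len(doc.text):
        raise ValueError(f"span {char_start}-{char_end} outside document")
    out = []
    for si, offsets in enumerate(doc.token_offsets):
        hit = [ti for ti, (s, e) in enumerate(offsets)
               if s < char_end and e > char_start]
        if hit:
            out.append((si, hit[0], hit[-1]))
    return out


def gold_token_spans(doc: Document, target_type: str = TARGET_TYPE,
                     collapse_discontinuous: bool = True,
                     ) -> set[tuple[int, int, int]]:
    """Token-level gold spans of the target annotation type.

    Discontinuous annotations are collapsed to their covering range by
    default; with ``collapse_discontinuous=False`` they are dropped.
    """
    spans: set[tuple[int, int, int]] = set()
    for ann in doc.annotations:
        if ann.type != target_type:
            continue
        if len(ann.fragments) > 1 and not collapse_discontinuous:
            continue
        spans.update(project_char_spans(doc, ann.start, ann.end))
    return spans


def gold_iob_labels(doc: Document, target_type: str = TARGET_TYPE,
                    ) -> list[list[str]]:
    """Per-sentence IOB label sequences for the target type."""
    labels = [["O"] * len(sent) for sent in doc.sentences]
    for si, ts, te in sorted(gold_token_spans(doc, target_type)):
        labels[si][ts] = "B"
        for ti in range(ts + 1, te + 1):
            labels[si][ti] = "I"
    return labels
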