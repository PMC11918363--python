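"""Word / wordpiece tokenisation and a tiny trainable transformer encoder.

The full-scale system plugs in a pretrained contextual encoder (BERT-class,
hidden size 768).  Everything in this package also runs with the
:class:`TinyTransformerEncoder` below: a small randomly-initialised
transformer trained from scratch, which keeps every experiment CPU-sized
while exercising the identical wordpiece alignment and fusion machinery.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .nn import Embedding, Module, TransformerLayer

logger = logging.getLogger(__name__)

__all__ = ["word_tokenize", "sentence_split", "WordPieceTokenizer",
           "EncodedInput", "TinyTransformerEncoder"]

_WORD_RE = re.compile(r"\w+(?:'\w+)?|[^\w\s]")
_SENT_RE = re.compile(r"[^.!?]*[.!?]+(?:\s+|$)|[^.!?]+$")

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"


def word_tokenize(text: str) -> list[tuple[str, int, int]]:
    """Rule-based word tokenizer returning (token, char_start, char_end)."""
    return [(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def sentence_split(text: str) -> list[tuple[int, int]]:
    """Split on sentence-final punctuation; returns char ranges."""
    spans = []
    for m in _SENT_RE.finditer(text):
        s, e = m.start(), m.end()
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append((s, e))
    return spans


@dataclass
class EncodedInput:
    """A sentence on the encoder's wordpiece grid.

    ``word_to_pieces`` maps each word index to its contiguous (start, end)
    wordpiece range (end exclusive); special and padding positions belong
    to no word.
    """

    piece_ids: np.ndarray            # (L,) int
    attention_mask: np.ndarray       # (L,) 1 for real pieces incl. CLS/SEP
    word_to_pieces: list[tuple[int, int]]
    pieces: list[str] = field(default_factory=list)


class WordPieceTokenizer:
    """Greedy longest-match subword tokenizer with ``##`` continuations.

    The vocabulary is built from a corpus: frequent whole words become
    single pieces; everything else decomposes into shorter pieces.  All
    single characters (and their ``##`` continuations) are always included,
    so any word tokenizes without falling back to ``[UNK]``.
    """

    def __init__(self, vocab: dict[str, int]):
        self.vocab = vocab
        self.ids = {PAD: vocab[PAD], UNK: vocab[UNK],
                    CLS: vocab[CLS], SEP: vocab[SEP]}
        self._max_piece = max((len(p.lstrip("#")) for p in vocab), default=1)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @classmethod
    def train(cls, texts: list[str], vocab_size: int = 800,
              min_freq: int = 2) -> "WordPieceTokenizer":
        from collections import Counter

        import string

        words: Counter[str] = Counter()
        # all letters/digits are always present so any alphanumeric word
        # decomposes into known pieces instead of [UNK]
        chars: set[str] = set(string.ascii_lowercase + string.digits)
        for text in texts:
            for tok, _, _ in word_tokenize(text):
                w = tok.lower()
                words[w] += 1
                chars.update(w)
        vocab: dict[str, int] = {}
        for special in (PAD, UNK, CLS, SEP):
            vocab[special] = len(vocab)
        for ch in sorted(chars):
            vocab[ch] = len(vocab)
            vocab["##" + ch] = len(vocab)
        # short prefixes/suffix pieces help unseen words share structure
        grams: Counter[str] = Counter()
        for w, c in words.items():
            for k in (2, 3):
                if len(w) > k:
                    grams[w[:k]] += c
                    grams["##" + w[-k:]] += c
        for piece, _ in grams.most_common():
            if len(vocab) >= vocab_size:
                break
            if piece not in vocab:
                vocab[piece] = len(vocab)
        for w, c in sorted(words.items(), key=lambda kv: (-kv[1], kv[0])):
            if len(vocab) >= vocab_size + len(words):
                break
            if c >= min_freq and w not in vocab:
                vocab[w] = len(vocab)
        return cls(vocab)

    def tokenize_word(self, word: str) -> list[str]:
        w = word.lower()
        pieces: list[str] = []
        pos = 0
        while pos < len(w):
            prefix = "##" if pos else ""
            end = min(len(w), pos + self._max_piece)
            piece = None
            while end > pos:
                cand = prefix + w[pos:end]
                if cand in self.vocab:
                    piece = cand
                    break
                end -= 1
            if piece is None:  # character not in vocab at all
                piece = UNK
                end = pos + 1
            pieces.append(piece)
            pos = end
        return pieces or [UNK]

    def encode_words(self, words: list[str], max_len: int = 64,
                     pad_to: int | None = None) -> EncodedInput:
        """Encode a pre-tokenized sentence: [CLS] pieces... [SEP] [PAD]..."""
        pieces = [CLS]
        ranges: list[tuple[int, int]] = []
        truncated = False
        for w in words:
            wp = self.tokenize_word(w)
            if len(pieces) + len(wp) > max_len - 1:
                truncated = True
                ranges.append((len(pieces), len(pieces)))  # empty range
                continue
            ranges.append((len(pieces), len(pieces) + len(wp)))
            pieces.extend(wp)
        pieces.append(SEP)
        if truncated:
            logger.warning("sentence truncated to %d wordpieces", max_len)
        L = pad_to if pad_to is not None else len(pieces)
        mask = np.zeros(L, dtype=np.int64)
        mask[:len(pieces)] = 1
        ids = np.full(L, self.vocab[PAD], dtype=np.int64)
        for i, p in enumerate(pieces):
            ids[i] = self.vocab.get(p, self.vocab[UNK])
        return EncodedInput(piece_ids=ids, attention_mask=mask,
                            word_to_pieces=ranges, pieces=pieces)


class TinyTransformerEncoder(Module):
    """A small from-scratch transformer producing per-wordpiece states.

    Parameters mirror the BERT family at reduced scale: learned token and
    position embeddings followed by post-LN self-attention blocks.  With
    ``hidden_size=768`` it emulates the interface of a full-size encoder;
    the test-scale default is much smaller.
    """

    def __init__(self, vocab_size: int, hidden_size: int = 32,
                 n_layers: int = 2, n_heads: int = 2, ffn_dim: int = 64,
                 max_len: int = 64, dropout: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden_size = hidden_size
        self.max_len = max_len
        self.tok_emb = Embedding(vocab_size, hidden_size, rng)
        self.pos_emb = Embedding(max_len, hidden_size, rng)
        self.layers = [TransformerLayer(hidden_size, n_heads, ffn_dim, rng,
                                        dropout=dropout)
                       for _ in range(n_layers)]

    def __call__(self, piece_ids: np.ndarray, attention_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        """piece_ids, attention_mask: (B, L) -> states (B, L, hidden)."""
        B, L = piece_ids.shape
        pos = np.broadcast_to(np.arange(L), (B, L))
        x = self.tok_emb(piece_ids) + self.pos_emb(pos)
        for layer in self.layers:
            x = layer(x, attention_mask, rng)
        return x

    def encode_texts(self, texts: list[str],
                     tokenizer: WordPieceTokenizer) -> np.ndarray:
        """Mean-pooled final-layer states for each text (deterministic)."""
        out = np.zeros((len(texts), self.hidden_size))
        for i, text in enumerate(texts):
            words = [t for t, _, _ in word_tokenize(text)]
            enc = tokenizer.encode_words(words, max_len=self.max_len)
            states = self(enc.piece_ids[None, :], enc.attention_mask[None, :])
            m = enc.attention_mask.astype(float)
            out[i] = (states.data[0] * m[:, None]).sum(0) / m.sum()
        return out
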