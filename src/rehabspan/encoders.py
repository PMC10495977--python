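"""Pluggable token encoders.

The span head only requires an object that maps a character window to an
n×d real matrix and exposes trainable parameters — in production that would
be a Chinese BERT-family encoder; this module ships :class:`TinyEncoder`, a
small trainable character-embedding + context-mixing stack that runs
comfortably on a single CPU. One tanh mixing layer over a width-3 window is
enough for each position to see its neighbours, which is what boundary
detection (is this character the first/last of an entity?) needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

PAD = "\x00"
UNK = "\x01"


class Encoder(Protocol):
    """Contract: text in, (n, d) representation matrix out, trainable."""

    d: int

    def encode(self, text: str) -> np.ndarray: ...


@dataclass
class TinyEncoder:
    """Character embedding + one width-3 tanh mixing layer.

    ``E_i = tanh(W · [emb(c_{i-1}); emb(c_i); emb(c_{i+1})] + b)`` with PAD
    embeddings at the boundaries. Unknown characters map to UNK.
    """

    vocab: dict[str, int]
    emb: np.ndarray   # (V, d_emb)
    W: np.ndarray     # (3*d_emb, d)
    b: np.ndarray     # (d,)

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def d_emb(self) -> int:
        return self.emb.shape[1]

    @classmethod
    def init(cls, charset, d: int = 32, d_emb: int | None = None,
             seed: int = 0) -> "TinyEncoder":
        if d_emb is None:
            d_emb = d
        vocab = {PAD: 0, UNK: 1}
        for ch in sorted(set(charset)):
            vocab.setdefault(ch, len(vocab))
        rng = np.random.default_rng(seed)
        return cls(
            vocab=vocab,
            emb=rng.normal(0.0, 0.1, (len(vocab), d_emb)),
            W=rng.normal(0.0, np.sqrt(1.0 / (3 * d_emb)), (3 * d_emb, d)),
            b=np.zeros(d),
        )

    @classmethod
    def from_corpus(cls, corpus, d: int = 32, seed: int = 0) -> "TinyEncoder":
        chars = set()
        for s in corpus:
            chars.update(s.text)
        return cls.init(chars, d=d, seed=seed)

    # -- forward / backward -------------------------------------------------

    def ids(self, text: str) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(c, unk) for c in text], dtype=np.int64)

    def _window(self, ids: np.ndarray) -> np.ndarray:
        padded = np.concatenate([[self.vocab[PAD]], ids, [self.vocab[PAD]]])
        rows = self.emb[padded]  # (n+2, d_emb)
        n = len(ids)
        return np.concatenate([rows[0:n], rows[1:n + 1], rows[2:n + 2]],
                              axis=1)  # (n, 3*d_emb)

    def encode(self, text: str) -> np.ndarray:
        if not text:
            return np.zeros((0, self.d))
        X = self._window(self.ids(text))
        return np.tanh(X @ self.W + self.b)

    def encode_with_cache(self, text: str):
        ids = self.ids(text)
        X = self._window(ids)
        H = np.tanh(X @ self.W + self.b)
        return H, (ids, X, H)

    def backward(self, dH: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. emb, W, b given dL/dE."""
        ids, X, H = cache
        dZ = dH * (1.0 - H * H)
        dW = X.T @ dZ
        db = dZ.sum(axis=0)
        dX = dZ @ self.W.T  # (n, 3*d_emb)
        de = self.d_emb
        demb = np.zeros_like(self.emb)
        padded = np.concatenate([[self.vocab[PAD]], ids, [self.vocab[PAD]]])
        n = len(ids)
        np.add.at(demb, padded[0:n], dX[:, :de])
        np.add.at(demb, padded[1:n + 1], dX[:, de:2 * de])
        np.add.at(demb, padded[2:n + 2], dX[:, 2 * de:])
        return {"emb": demb, "W": dW, "b": db}

    def params(self) -> dict[str, np.ndarray]:
        return {"emb": self.emb, "W": self.W, "b": self.b}

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "encoder.npz", emb=self.emb, W=self.W, b=self.b)
        (directory / "encoder.json").write_text(json.dumps(
            {"format": "rehabspan-tiny-encoder-v1",
             "vocab": {c: i for c, i in self.vocab.items()}},
            ensure_ascii=False))

    @classmethod
    def load(cls, directory) -> "TinyEncoder":
        directory = Path(directory)
        meta = json.loads((directory / "encoder.json").read_text())
        data = np.load(directory / "encoder.npz")
        return cls(vocab={c: int(i) for c, i in meta["vocab"].items()},
                   emb=data["emb"], W=data["W"], b=data["b"])
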