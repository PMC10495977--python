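"""Per-position softmax BIO tagging head — the flat sequence-labeling baseline.

A single linear projection of the representation matrix onto ``2·C + 1``
BIO tags (O, B-label, I-label per category), trained with cross-entropy and
decoded by per-position argmax followed by BIO-to-span conversion. By
construction it assigns one tag per character, so it can never emit a span
nested inside another — the structural limitation the span head removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import AnnotatedSentence, EntitySpan, EntityTypeSchema, from_bio, to_bio
from .span_model import softmax_rows


def bio_tag_list(schema: EntityTypeSchema) -> list[str]:
    tags = ["O"]
    for lab in schema.labels:
        tags.append(f"B-{lab}")
        tags.append(f"I-{lab}")
    return tags


@dataclass
class BaselineHead:
    """Linear BIO tag projection: logits = E · W + b."""

    schema: EntityTypeSchema
    W: np.ndarray  # (d, 2C+1)
    b: np.ndarray  # (2C+1,)

    @classmethod
    def init(cls, schema: EntityTypeSchema, d: int,
             rng: np.random.Generator, scale: float = 0.02) -> "BaselineHead":
        k = 2 * len(schema) + 1
        return cls(schema=schema, W=rng.normal(0.0, scale, (d, k)),
                   b=np.zeros(k))

    @property
    def tags(self) -> list[str]:
        return bio_tag_list(self.schema)

    def logits(self, E: np.ndarray) -> np.ndarray:
        return E @ self.W + self.b

    def loss_and_grads(self, E: np.ndarray, gold_tags: np.ndarray):
        """Mean position cross-entropy; returns (loss, grads, dE)."""
        n = len(E)
        P = softmax_rows(self.logits(E))
        idx = np.arange(n)
        loss = float(-np.log(P[idx, gold_tags] + 1e-12).mean())
        dZ = P.copy()
        dZ[idx, gold_tags] -= 1.0
        dZ /= max(n, 1)
        return loss, {"W": E.T @ dZ, "b": dZ.sum(axis=0)}, dZ @ self.W.T

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "baseline_head.npz", W=self.W, b=self.b)
        (directory / "baseline_head.json").write_text(json.dumps(
            {"format": "rehabspan-baseline-v1",
             "schema": list(self.schema.labels)}, ensure_ascii=False))

    @classmethod
    def load(cls, directory) -> "BaselineHead":
        directory = Path(directory)
        meta = json.loads((directory / "baseline_head.json").read_text())
        data = np.load(directory / "baseline_head.npz")
        return cls(schema=EntityTypeSchema(tuple(meta["schema"])),
                   W=data["W"], b=data["b"])


def gold_tag_ids(sentence: AnnotatedSentence, head: BaselineHead) -> np.ndarray:
    """Gold BIO tag ids for training; nested spans are flattened by to_bio."""
    import warnings
    tag_index = {t: i for i, t in enumerate(head.tags)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nested-drop warnings counted elsewhere
        tags = to_bio(sentence)
    return np.array([tag_index[t] for t in tags], dtype=np.int64)


def softmax_baseline_decode(E: np.ndarray, head: BaselineHead,
                            text: str) -> list[EntitySpan]:
    """Argmax BIO tags converted to spans; structurally nesting-free."""
    if len(E) == 0:
        return []
    tag_ids = np.argmax(head.logits(E), axis=1)
    tags = [head.tags[t] for t in tag_ids]
    sent = from_bio(list(text), tags, head.schema, sentence_id="decode")
    return list(sent.entities)
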