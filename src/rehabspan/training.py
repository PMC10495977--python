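"""Fine-tuning harness: Adam, warmup/decay schedule, span and baseline
training loops, checkpointing, and self-training augmentation.

Defaults follow the conventional fine-tuning recipe for this task family:
Adam at an initial learning rate of 2e-5 with warmup proportion 0.15, batch
size 8, 20 epochs. (The tiny CPU encoder used in tests wants a much larger
learning rate; every value is overridable, and the committed defaults file
``defaults.yaml`` is the single source of "default" settings.)

Runs are bit-reproducible for a fixed seed: batch order, target subsampling
and parameter initialisation all draw from generators derived from the
configured seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import span_model
from .baseline import BaselineHead, gold_tag_ids, softmax_baseline_decode
from .corpus_io import AnnotatedSentence, Corpus, EntitySpan, EntityTypeSchema
from .encoders import TinyEncoder
from .span_model import (DEFAULT_MAX_SPAN_LEN, DEFAULT_THRESHOLD, LossConfig,
                         SpanHead, build_targets, decode_entities,
                         forward_backward)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 2e-5
    warmup_proportion: float = 0.15
    batch_size: int = 8
    epochs: int = 20
    max_seq_len: int = 128
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"
    max_pairs: int = 50          # candidate-pair sample cap per sentence
    decay: str = "linear"        # post-warmup schedule: "linear" or "constant"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.warmup_proportion < 1.0):
            raise ValueError("warmup_proportion must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def lr_multiplier(step: int, total_steps: int, warmup_proportion: float,
                  decay: str = "linear") -> float:
    """Learning-rate schedule multiplier at 0-indexed ``step``.

    Rises linearly from 0 to 1 over the first ``warmup_proportion`` of the
    total steps, then decays linearly to 0 by the final step (or stays at 1
    with ``decay="constant"``).
    """
    warm = int(round(total_steps * warmup_proportion))
    if step < warm:
        return (step + 1) / warm
    if decay == "constant" or total_steps <= warm:
        return 1.0
    rest = total_steps - warm
    return max(0.0, (total_steps - step) / rest)


class Adam:
    """Plain Adam over a flat dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * lr_scale * mhat / (np.sqrt(vhat) + self.eps)


def _truncate(sentence: AnnotatedSentence, max_len: int) -> AnnotatedSentence:
    if len(sentence.text) <= max_len:
        return sentence
    kept = tuple(e for e in sentence.entities if e.end <= max_len)
    for e in sentence.entities:
        if e.end > max_len:
            logger.warning("sentence %r: span %s crosses the %d-character "
                           "window boundary and was dropped",
                           sentence.id, e.key(), max_len)
    return replace(sentence, text=sentence.text[:max_len], entities=kept)


@dataclass
class SpanNerModel:
    """Trained encoder + span head plus decode settings; the unit a
    checkpoint stores."""

    encoder: TinyEncoder
    head: SpanHead
    max_span_len: int = DEFAULT_MAX_SPAN_LEN
    threshold: float = DEFAULT_THRESHOLD

    @property
    def schema(self) -> EntityTypeSchema:
        return self.head.schema

    def predict_spans(self, text: str) -> list[EntitySpan]:
        E = self.encoder.encode(text)
        if len(E) == 0:
            return []
        return decode_entities(E, self.head, max_span_len=self.max_span_len,
                               threshold=self.threshold, text=text)

    def predict(self, sentence: AnnotatedSentence) -> AnnotatedSentence:
        return replace(sentence, entities=tuple(self.predict_spans(sentence.text)))

    def predict_corpus(self, corpus: Corpus) -> Corpus:
        return Corpus(sentences=[self.predict(s) for s in corpus],
                      schema=self.schema)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.encoder.save(directory)
        span_model.save_head(self.head, directory)
        (directory / "manifest.json").write_text(json.dumps(
            {"format": "rehabspan-checkpoint-v1",
             "encoder": "tiny", "d": self.head.d,
             "max_span_len": self.max_span_len,
             "threshold": self.threshold,
             "schema": list(self.schema.labels)},
            ensure_ascii=False, indent=1))

    @classmethod
    def load(cls, directory) -> "SpanNerModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        return cls(encoder=TinyEncoder.load(directory),
                   head=span_model.load_head(directory),
                   max_span_len=int(manifest["max_span_len"]),
                   threshold=float(manifest["threshold"]))


def train(corpus: Corpus, encoder: TinyEncoder, cfg: TrainConfig,
          max_span_len: int = DEFAULT_MAX_SPAN_LEN,
          threshold: float = DEFAULT_THRESHOLD,
          ) -> tuple[SpanNerModel, list[dict]]:
    """Train the span head (and encoder) on a gold corpus.

    Returns the trained model and a per-epoch loss log with the mean total
    loss and its start/end/span components.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(cfg.seed)
    head = SpanHead.init(corpus.schema, encoder.d, rng)

    sentences = [_truncate(s, cfg.max_seq_len) for s in corpus]
    targets = [build_targets(s, corpus.schema, max_pairs=cfg.max_pairs,
                             seed=int(rng.integers(2 ** 31)))
               for s in sentences]

    params: dict[str, np.ndarray] = {}
    for name, arr in encoder.params().items():
        params[f"enc.{name}"] = arr
    for li, lab in enumerate(corpus.schema.labels):
        for name, arr in head.heads[lab].arrays().items():
            params[f"head.{li}.{name}"] = arr
    opt = Adam(params, lr=cfg.learning_rate)

    n = len(sentences)
    steps_per_epoch = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = steps_per_epoch * cfg.epochs
    step = 0
    log: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-pair warnings during training
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses, epoch_comps = [], []
            for b0 in range(0, n, cfg.batch_size):
                batch = order[b0:b0 + cfg.batch_size]
                grads = {k: np.zeros_like(v) for k, v in params.items()}
                for si in batch:
                    s, tgt = sentences[si], targets[si]
                    if not s.text:
                        continue
                    E, cache = encoder.encode_with_cache(s.text)
                    loss, comps, hgrads, dE = forward_backward(
                        E, head, tgt, cfg.loss)
                    enc_grads = encoder.backward(dE, cache)
                    scale = 1.0 / len(batch)
                    for name, g in enc_grads.items():
                        grads[f"enc.{name}"] += scale * g
                    for li, lab in enumerate(corpus.schema.labels):
                        for name, g in hgrads[lab].items():
                            grads[f"head.{li}.{name}"] += scale * g
                    epoch_losses.append(loss)
                    epoch_comps.append(comps)
                opt.step(grads, lr_scale=lr_multiplier(
                    step, total_steps, cfg.warmup_proportion, cfg.decay))
                step += 1
            mean = lambda key: (float(np.mean([c[key] for c in epoch_comps]))
                                if epoch_comps else 0.0)
            entry = {"epoch": epoch + 1,
                     "loss": float(np.mean(epoch_losses)) if epoch_losses else 0.0,
                     "loss_start": mean("start"), "loss_end": mean("end"),
                     "loss_span": mean("span"),
                     "lr_multiplier": lr_multiplier(
                         step - 1, total_steps, cfg.warmup_proportion, cfg.decay)}
            log.append(entry)
            logger.info("epoch %d: loss=%.4f (start=%.4f end=%.4f span=%.4f)",
                        entry["epoch"], entry["loss"], entry["loss_start"],
                        entry["loss_end"], entry["loss_span"])
    model = SpanNerModel(encoder=encoder, head=head,
                         max_span_len=max_span_len, threshold=threshold)
    return model, log


def train_softmax_baseline(corpus: Corpus, encoder: TinyEncoder,
                           cfg: TrainConfig) -> tuple[tuple[TinyEncoder, BaselineHead], list[dict]]:
    """Train the per-position softmax BIO baseline with the same schedule."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(cfg.seed)
    head = BaselineHead.init(corpus.schema, encoder.d, rng)
    sentences = [_truncate(s, cfg.max_seq_len) for s in corpus]
    gold = [gold_tag_ids(s, head) for s in sentences]

    params = {f"enc.{k}": v for k, v in encoder.params().items()}
    params.update({f"head.{k}": v for k, v in head.params().items()})
    opt = Adam(params, lr=cfg.learning_rate)

    n = len(sentences)
    steps_per_epoch = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = steps_per_epoch * cfg.epochs
    step = 0
    log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b0 in range(0, n, cfg.batch_size):
            batch = order[b0:b0 + cfg.batch_size]
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for si in batch:
                s = sentences[si]
                if not s.text:
                    continue
                E, cache = encoder.encode_with_cache(s.text)
                loss, hgrads, dE = head.loss_and_grads(E, gold[si])
                enc_grads = encoder.backward(dE, cache)
                scale = 1.0 / len(batch)
                for name, g in enc_grads.items():
                    grads[f"enc.{name}"] += scale * g
                for name, g in hgrads.items():
                    grads[f"head.{name}"] += scale * g
                epoch_losses.append(loss)
            opt.step(grads, lr_scale=lr_multiplier(
                step, total_steps, cfg.warmup_proportion, cfg.decay))
            step += 1
        log.append({"epoch": epoch + 1,
                    "loss": float(np.mean(epoch_losses)) if epoch_losses else 0.0})
    return (encoder, head), log


def self_train_augment(model: SpanNerModel, unlabeled: list[str],
                       base: Corpus,
                       min_match_prob: float | None = None) -> Corpus:
    """Pseudo-label unlabeled sentences and append them to the base corpus.

    Each unlabeled sentence is decoded with the trained model and tagged
    ``source="model"`` so downstream reports can separate manual from
    model annotation. No confidence filter is applied by default; pass
    ``min_match_prob`` to decode with a stricter acceptance threshold.
    """
    threshold = (model.threshold if min_match_prob is None
                 else max(model.threshold, min_match_prob))
    out = list(base.sentences)
    existing = {s.id for s in out}
    for i, text in enumerate(unlabeled):
        sid = f"model-{i}"
        while sid in existing:
            sid = f"model-{i}-{len(existing)}"
        existing.add(sid)
        E = model.encoder.encode(text)
        spans = (decode_entities(E, model.head, model.max_span_len,
                                 threshold, text=text) if len(E) else [])
        out.append(AnnotatedSentence(id=sid, text=text,
                                     entities=tuple(spans), source="model"))
    return Corpus(sentences=out, schema=base.schema)
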