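"""Boundary-prediction span head for nested-capable entity recognition.

The head operates on an encoder's representation matrix ``E`` (n positions ×
d dimensions, one row per character). For each entity category it

1. predicts per-position *start* probabilities ``P_start = softmax(E · T_start)``
   (row-wise, two classes: boundary / not);
2. injects the start information into the representation — the start
   indicator one-hot is embedded into d dimensions by a learned 2×d matrix
   and added row-wise — and predicts *end* probabilities the same way;
3. extracts candidate start/end indices as the positions whose class-1
   probability wins the row argmax (ties resolve to non-boundary);
4. scores every admissible (start, end) candidate pair with a sigmoid
   binary classifier ``sigmoid(m · concat(E_i, E_j))`` and accepts pairs
   above a threshold.

Because accepted pairs may overlap or nest freely, the decoder can emit
nested entities that per-token BIO tagging structurally cannot.

Training minimises ``L = α·L_start + β·L_end + γ·L_span`` — mean
cross-entropies over boundary positions plus mean binary cross-entropy over
sampled candidate pairs. The start indicator uses gold labels during
training (teacher forcing) and the model's own argmax at inference.

Note a structural property of the pair scorer: its logit is additive,
``f(i) + g(j)``, so two same-category gold pairs with four distinct
boundaries force their two crossing pairs above threshold as well.
Same-category nesting is exactly decodable when the nested pair shares a
boundary; cross-category nesting is always exactly decodable because
categories are scored independently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import AnnotatedSentence, Corpus, EntitySpan, EntityTypeSchema

logger = logging.getLogger(__name__)

DEFAULT_MAX_SPAN_LEN = 30
DEFAULT_THRESHOLD = 0.5


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, None, 500))),
                    np.exp(np.clip(z, -500, None))
                    / (1.0 + np.exp(np.clip(z, -500, None))))


@dataclass
class LossConfig:
    """Weights of the three loss components (start, end, span matching)."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class CategoryHead:
    """Trainable parameters of one entity category's span head."""

    T_start: np.ndarray  # (d, 2)
    T_end: np.ndarray    # (d, 2)
    U: np.ndarray        # (2, d) start-indicator embedding
    m: np.ndarray        # (2d,) pair-matching weights

    @classmethod
    def init(cls, d: int, rng: np.random.Generator,
             scale: float = 0.02) -> "CategoryHead":
        return cls(
            T_start=rng.normal(0.0, scale, (d, 2)),
            T_end=rng.normal(0.0, scale, (d, 2)),
            U=rng.normal(0.0, scale, (2, d)),
            m=rng.normal(0.0, scale, (2 * d,)),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {"T_start": self.T_start, "T_end": self.T_end,
                "U": self.U, "m": self.m}


@dataclass
class SpanHead:
    """One :class:`CategoryHead` per schema label, over width-d representations."""

    schema: EntityTypeSchema
    d: int
    heads: dict[str, CategoryHead]

    @classmethod
    def init(cls, schema: EntityTypeSchema, d: int,
             rng: np.random.Generator) -> "SpanHead":
        return cls(schema=schema, d=d,
                   heads={lab: CategoryHead.init(d, rng)
                          for lab in schema.labels})


# ---------------------------------------------------------------------------
# Forward operations

def _check_finite(E: np.ndarray) -> None:
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("non-finite entries in representation matrix")


def predict_start(E: np.ndarray, head: CategoryHead) -> np.ndarray:
    """Row-stochastic (n, 2) start-boundary probabilities for one category."""
    _check_finite(E)
    return softmax_rows(E @ head.T_start)


def start_indicator(P_start: np.ndarray) -> np.ndarray:
    """(n, 2) one-hot of the row argmax; the 0.5/0.5 tie resolves to class 0."""
    is_start = P_start[:, 1] > P_start[:, 0]
    out = np.zeros_like(P_start)
    out[np.arange(len(P_start)), is_start.astype(int)] = 1.0
    return out


def indicator_from_labels(y: np.ndarray) -> np.ndarray:
    """(n, 2) one-hot from 0/1 position labels (teacher forcing input)."""
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), y.astype(int)] = 1.0
    return out


def predict_end(E: np.ndarray, indicator: np.ndarray,
                head: CategoryHead) -> np.ndarray:
    """End-boundary probabilities given a start indicator.

    The (n, 2) indicator is embedded into d dimensions through ``U`` and
    added to ``E`` row-wise before the end projection, so each row's logits
    depend only on its own representation and indicator.
    """
    if indicator.shape != (len(E), 2):
        raise ValueError(
            f"indicator shape {indicator.shape} != {(len(E), 2)}"
        )
    return softmax_rows((E + indicator @ head.U) @ head.T_end)


@dataclass(frozen=True)
class CandidateIndices:
    starts: frozenset[int]
    ends: frozenset[int]


def extract_indices(P: np.ndarray) -> frozenset[int]:
    """Positions whose class-1 probability strictly wins the row argmax."""
    return frozenset(np.flatnonzero(P[:, 1] > P[:, 0]).tolist())


def match_pair(E: np.ndarray, i_start: int, j_end: int,
               head: CategoryHead) -> float:
    """Sigmoid matching probability for the candidate boundary pair (i, j)."""
    if i_start > j_end:
        raise ValueError(f"start {i_start} after end {j_end}")
    x = np.concatenate([E[i_start], E[j_end]])
    return float(sigmoid(head.m @ x))


def decode_entities(E: np.ndarray, span_head: SpanHead,
                    max_span_len: int = DEFAULT_MAX_SPAN_LEN,
                    threshold: float = DEFAULT_THRESHOLD,
                    text: str | None = None) -> list[EntitySpan]:
    """Nested-capable decoding over all categories.

    For each category independently: candidate starts and ends come from the
    boundary argmax rule; every pair with ``i <= j`` and ``j - i <
    max_span_len`` whose matching probability strictly exceeds ``threshold``
    becomes an entity ``[i, j+1)``. Accepted spans are all retained, so
    overlap and nesting pass through. When ``text`` is given surfaces are
    sliced from it; otherwise a placeholder of the right length is used.
    """
    spans: list[EntitySpan] = []
    for label in span_head.schema.labels:
        head = span_head.heads[label]
        P_s = predict_start(E, head)
        P_e = predict_end(E, start_indicator(P_s), head)
        starts = sorted(extract_indices(P_s))
        ends = sorted(extract_indices(P_e))
        for i in starts:
            for j in ends:
                if j < i or j - i >= max_span_len:
                    continue
                if match_pair(E, i, j, head) > threshold:
                    end = j + 1
                    surface = (text[i:end] if text is not None
                               else "·" * (end - i))
                    spans.append(EntitySpan(label, i, end, surface))
    spans.sort(key=lambda s: (s.start, s.end, s.label))
    return spans


# ---------------------------------------------------------------------------
# Targets and loss

@dataclass
class CategoryTargets:
    y_start: np.ndarray  # (n,) 0/1
    y_end: np.ndarray    # (n,) 0/1
    pairs: list[tuple[int, int, int]]  # (i, j, label in {0,1})


@dataclass
class SpanTargets:
    """Gold boundary labels and sampled candidate pairs, per category."""

    n: int
    per_category: dict[str, CategoryTargets]


def build_targets(sentence: AnnotatedSentence, schema: EntityTypeSchema,
                  n: int | None = None, max_pairs: int = 50,
                  seed: int = 0) -> SpanTargets:
    """Derive training targets from a gold sentence.

    Positive pairs are the gold (start, end) boundary pairs. Negative pairs
    are every combination of a gold start with a gold end of the same
    category (i <= j) that is not itself a gold pair — the hard negatives
    the matcher must reject. The pair sample is capped at ``max_pairs`` per
    sentence with seed-deterministic subsampling.
    """
    if n is None:
        n = len(sentence.text)
    rng = np.random.default_rng(seed)
    per_cat: dict[str, CategoryTargets] = {}
    for label in schema.labels:
        ents = [e for e in sentence.entities
                if e.label == label and e.end <= n]
        y_s = np.zeros(n)
        y_e = np.zeros(n)
        gold_pairs = set()
        for e in ents:
            y_s[e.start] = 1
            y_e[e.end - 1] = 1
            gold_pairs.add((e.start, e.end - 1))
        pairs = [(i, j, 1) for (i, j) in sorted(gold_pairs)]
        starts = sorted({i for i, _ in gold_pairs})
        ends = sorted({j for _, j in gold_pairs})
        negs = [(i, j, 0) for i in starts for j in ends
                if i <= j and (i, j) not in gold_pairs]
        pairs.extend(negs)
        if len(pairs) > max_pairs:
            keep = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[k] for k in sorted(keep)]
        per_cat[label] = CategoryTargets(y_start=y_s, y_end=y_e, pairs=pairs)
    return SpanTargets(n=n, per_category=per_cat)


@dataclass
class SpanPredictions:
    """Per-category probabilities for one sentence (teacher-forced P_end)."""

    p_start: dict[str, np.ndarray]
    p_end: dict[str, np.ndarray]
    p_pairs: dict[str, np.ndarray]  # matching probability per sampled pair


_EPS = 1e-12


def compute_loss(pred: SpanPredictions, targets: SpanTargets,
                 cfg: LossConfig) -> tuple[float, dict[str, float]]:
    """Composite loss ``α·L_start + β·L_end + γ·L_span``.

    ``L_start``/``L_end`` are mean cross-entropies over all (category,
    position) cells; ``L_span`` is mean binary cross-entropy over all
    sampled pairs. Zero exactly when every prediction puts probability one
    on its label.
    """
    labels = list(targets.per_category)
    n = targets.n
    ce_s = ce_e = 0.0
    pair_ce = []
    for lab in labels:
        tgt = targets.per_category[lab]
        ps = pred.p_start[lab]
        pe = pred.p_end[lab]
        idx = np.arange(n)
        ce_s += -np.log(ps[idx, tgt.y_start.astype(int)] + _EPS).sum()
        ce_e += -np.log(pe[idx, tgt.y_end.astype(int)] + _EPS).sum()
        pp = pred.p_pairs[lab]
        for (_, _, y), p in zip(tgt.pairs, pp):
            pair_ce.append(-np.log((p if y else 1 - p) + _EPS))
    denom = max(len(labels) * n, 1)
    l_start = ce_s / denom
    l_end = ce_e / denom
    if pair_ce:
        l_span = float(np.mean(pair_ce))
    else:
        l_span = 0.0
        if cfg.gamma > 0:
            warnings.warn("empty candidate-pair sample; L_span = 0",
                          stacklevel=2)
    total = cfg.alpha * l_start + cfg.beta * l_end + cfg.gamma * l_span
    return float(total), {"start": float(l_start), "end": float(l_end),
                          "span": float(l_span)}


def forward(E: np.ndarray, span_head: SpanHead, targets: SpanTargets,
            teacher_forcing: bool = True) -> SpanPredictions:
    """Probabilities for every category of one sentence, given targets."""
    p_start, p_end, p_pairs = {}, {}, {}
    for lab in span_head.schema.labels:
        head = span_head.heads[lab]
        tgt = targets.per_category[lab]
        ps = predict_start(E, head)
        ind = (indicator_from_labels(tgt.y_start) if teacher_forcing
               else start_indicator(ps))
        pe = predict_end(E, ind, head)
        pp = np.array([match_pair(E, i, j, head) for i, j, _ in tgt.pairs])
        p_start[lab], p_end[lab], p_pairs[lab] = ps, pe, pp
    return SpanPredictions(p_start=p_start, p_end=p_end, p_pairs=p_pairs)


def forward_backward(E: np.ndarray, span_head: SpanHead,
                     targets: SpanTargets, cfg: LossConfig):
    """Loss, its components, head-parameter gradients, and dL/dE.

    Teacher forcing throughout: the end head sees the gold start indicator.
    Gradients use the standard softmax/sigmoid cross-entropy identities.
    """
    n = targets.n
    labels = list(span_head.schema.labels)
    denom = max(len(labels) * n, 1)
    n_pairs_total = sum(len(targets.per_category[l].pairs) for l in labels)

    pred = forward(E, span_head, targets, teacher_forcing=True)
    total, comps = compute_loss(pred, targets, cfg)

    dE = np.zeros_like(E)
    grads: dict[str, dict[str, np.ndarray]] = {}
    idx = np.arange(n)
    for lab in labels:
        head = span_head.heads[lab]
        tgt = targets.per_category[lab]
        d = span_head.d

        # start branch
        ys1 = np.zeros((n, 2))
        ys1[idx, tgt.y_start.astype(int)] = 1.0
        dZs = (pred.p_start[lab] - ys1) * (cfg.alpha / denom)
        dT_start = E.T @ dZs
        dE += dZs @ head.T_start.T

        # end branch (teacher-forced indicator)
        ind = indicator_from_labels(tgt.y_start)
        E2 = E + ind @ head.U
        ye1 = np.zeros((n, 2))
        ye1[idx, tgt.y_end.astype(int)] = 1.0
        dZe = (pred.p_end[lab] - ye1) * (cfg.beta / denom)
        dT_end = E2.T @ dZe
        dE2 = dZe @ head.T_end.T
        dU = ind.T @ dE2
        dE += dE2

        # pair-matching branch
        dm = np.zeros_like(head.m)
        if n_pairs_total and cfg.gamma > 0:
            for (i, j, y), p in zip(tgt.pairs, pred.p_pairs[lab]):
                dz = (p - y) * (cfg.gamma / n_pairs_total)
                x = np.concatenate([E[i], E[j]])
                dm += dz * x
                dE[i] += dz * head.m[:d]
                dE[j] += dz * head.m[d:]

        grads[lab] = {"T_start": dT_start, "T_end": dT_end, "U": dU, "m": dm}

    return total, comps, grads, dE


# ---------------------------------------------------------------------------
# Checkpointing

def save_head(span_head: SpanHead, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for li, lab in enumerate(span_head.schema.labels):
        for name, arr in span_head.heads[lab].arrays().items():
            arrays[f"cat{li}__{name}"] = arr
    np.savez(directory / "span_head.npz", **arrays)
    manifest = {"format": "rehabspan-head-v1", "d": span_head.d,
                "schema": list(span_head.schema.labels)}
    (directory / "head.json").write_text(
        json.dumps(manifest, ensure_ascii=False, indent=1))


def load_head(directory) -> SpanHead:
    directory = Path(directory)
    manifest = json.loads((directory / "head.json").read_text())
    schema = EntityTypeSchema(tuple(manifest["schema"]))
    data = np.load(directory / "span_head.npz")
    heads = {}
    for li, lab in enumerate(schema.labels):
        heads[lab] = CategoryHead(
            T_start=data[f"cat{li}__T_start"],
            T_end=data[f"cat{li}__T_end"],
            U=data[f"cat{li}__U"],
            m=data[f"cat{li}__m"],
        )
    return SpanHead(schema=schema, d=int(manifest["d"]), heads=heads)
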