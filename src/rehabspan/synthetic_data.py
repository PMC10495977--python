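"""Seed-deterministic synthetic span-annotated corpora.

The generator emulates the structural features that make rehabilitation-
medicine text hard for flat sequence labeling — long entities, nested
entities, and a heavy tail of surface forms seen only once — without any
pretence of linguistic realism. Sentences are strings over per-type
character alphabets (disjoint CJK blocks by default, so surface→type is
separable and memorizable by a small encoder; a shared-alphabet "hard" mode
removes that separability).

Low-frequency control: per type, surfaces are drawn from a rank-ordered
vocabulary with a truncated power law ``p_k ∝ k^{-s}``; the exponent ``s``
is solved numerically so that the expected fraction of mentions whose
surface occurs exactly once matches the configured target.

Nested sentences embed an inner entity of a different type strictly inside
an outer entity, the configuration BIO tagging cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .annotation_qa import low_frequency_analysis
from .corpus_io import (AnnotatedSentence, Corpus, EntitySpan,
                        EntityTypeSchema)

_CJK_BASE = 0x4E00
_BLOCK = 48  # characters per type alphabet


@dataclass
class SynthConfig:
    n_sentences: int = 200
    schema: EntityTypeSchema = field(default_factory=EntityTypeSchema)
    vocab_size: int = 80                # surfaces per type
    entity_len_range: tuple[int, int] = (2, 8)
    entities_per_sentence: int = 2
    nesting_rate: float = 0.1           # fraction of sentences with a nested pair
    low_freq_target: float = 0.25       # target singleton-mention proportion
    sentence_len_range: tuple[int, int] = (20, 40)
    distinct_types_per_sentence: bool = True
    hard_mode: bool = False             # shared alphabet: no surface separability
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.nesting_rate <= 1.0):
            raise ValueError("nesting_rate must be in [0, 1]")
        if not (0.0 <= self.low_freq_target <= 1.0):
            raise ValueError("low_freq_target must be in [0, 1]")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if min(self.entity_len_range) < 1 or min(self.sentence_len_range) < 1:
            raise ValueError("length ranges must be positive")
        # an entity plus one character of padding on each side must fit
        if self.entity_len_range[1] + 2 > self.sentence_len_range[0]:
            raise ValueError(
                "entities of maximal length cannot fit in the shortest "
                "sentence; enlarge sentence_len_range or shrink entities"
            )


def _alphabet(type_index: int, hard: bool) -> str:
    base = _CJK_BASE if hard else _CJK_BASE + type_index * _BLOCK
    return "".join(chr(base + i) for i in range(_BLOCK))


def _filler_alphabet(n_types: int, hard: bool) -> str:
    base = _CJK_BASE if hard else _CJK_BASE + n_types * _BLOCK
    return "".join(chr(base + i) for i in range(_BLOCK))


def singleton_proportion(p: np.ndarray, m: int) -> float:
    """Expected fraction of i.i.d. mentions whose surface appears exactly once.

    With draw distribution ``p`` and ``m`` mentions, the expected number of
    rank-k mentions that end up singletons is ``m p_k (1-p_k)^{m-1}``; the
    proportion divides by ``m``.
    """
    if m <= 1:
        return 1.0
    return float(np.sum(p * (1.0 - p) ** (m - 1)))


def solve_powerlaw_exponent(vocab_size: int, mentions: int,
                            target: float) -> float:
    """Exponent s of ``p_k ∝ k^{-s}`` hitting the target singleton proportion.

    The proportion is decreasing in s (a steeper law concentrates mentions
    on few surfaces); the root is bracketed on [0, 12] and clamped to the
    nearest endpoint when the target is unreachable for this vocabulary
    size and mention count.
    """
    ranks = np.arange(1, vocab_size + 1, dtype=float)

    def prop(s: float) -> float:
        w = ranks ** (-s)
        return singleton_proportion(w / w.sum(), mentions)

    lo, hi = 0.0, 12.0
    if prop(lo) <= target:
        return lo
    if prop(hi) >= target:
        return hi
    return float(brentq(lambda s: prop(s) - target, lo, hi, xtol=1e-6))


def _make_vocab(rng: np.random.Generator, alphabet: str, size: int,
                len_range: tuple[int, int]) -> list[str]:
    vocab: list[str] = []
    seen = set()
    attempts = 0
    while len(vocab) < size and attempts < size * 200:
        attempts += 1
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        surf = "".join(rng.choice(list(alphabet), size=ln))
        if surf not in seen:
            seen.add(surf)
            vocab.append(surf)
    if len(vocab) < size:
        raise ValueError("could not build a distinct vocabulary; alphabet "
                         "too small for the requested size")
    return vocab


def _place(rng: np.random.Generator, occupied: list[tuple[int, int]],
           length: int, sent_len: int) -> int | None:
    """Random slot for a span of ``length`` leaving a 1-char gap to others."""
    slots = []
    for start in range(0, sent_len - length + 1):
        end = start + length
        if all(end + 1 <= s or start >= e + 1 for s, e in occupied):
            slots.append(start)
    if not slots:
        return None
    return int(rng.choice(slots))


def generate(cfg: SynthConfig) -> tuple[Corpus, dict]:
    """Generate a corpus plus a manifest of realized statistics."""
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.schema.labels)
    n_types = len(labels)
    alphabets = {lab: _alphabet(i, cfg.hard_mode)
                 for i, lab in enumerate(labels)}
    filler = _filler_alphabet(n_types, cfg.hard_mode)

    vocabs = {lab: _make_vocab(rng, alphabets[lab], cfg.vocab_size,
                               cfg.entity_len_range)
              for lab in labels}
    expected_mentions = max(
        2, round(cfg.n_sentences * cfg.entities_per_sentence / n_types))
    exponents, draw_p = {}, {}
    for lab in labels:
        s = solve_powerlaw_exponent(cfg.vocab_size, expected_mentions,
                                    cfg.low_freq_target)
        w = np.arange(1, cfg.vocab_size + 1, dtype=float) ** (-s)
        exponents[lab] = s
        draw_p[lab] = w / w.sum()

    sentences: list[AnnotatedSentence] = []
    n_nested = 0
    n_skipped_placements = 0
    for si in range(cfg.n_sentences):
        sent_len = int(rng.integers(cfg.sentence_len_range[0],
                                    cfg.sentence_len_range[1] + 1))
        chars = list(rng.choice(list(filler), size=sent_len))
        occupied: list[tuple[int, int]] = []
        entities: list[EntitySpan] = []

        nested_here = (cfg.nesting_rate > 0
                       and rng.random() < cfg.nesting_rate and n_types >= 2)
        if nested_here:
            outer_i, inner_i = rng.choice(n_types, size=2, replace=False)
            outer_lab, inner_lab = labels[int(outer_i)], labels[int(inner_i)]
            inner_surf = vocabs[inner_lab][
                int(rng.choice(cfg.vocab_size, p=draw_p[inner_lab]))]
            pad = alphabets[outer_lab]
            pre = "".join(rng.choice(list(pad), size=int(rng.integers(1, 3))))
            suf = "".join(rng.choice(list(pad), size=int(rng.integers(1, 3))))
            outer_surf = pre + inner_surf + suf
            start = _place(rng, occupied, len(outer_surf), sent_len)
            if start is None:
                n_skipped_placements += 1
                nested_here = False
            else:
                end = start + len(outer_surf)
                chars[start:end] = list(outer_surf)
                occupied.append((start, end))
                entities.append(EntitySpan(outer_lab, start, end, outer_surf))
                i0 = start + len(pre)
                entities.append(EntitySpan(inner_lab, i0,
                                           i0 + len(inner_surf), inner_surf))
                n_nested += 1

        if cfg.distinct_types_per_sentence:
            k = min(cfg.entities_per_sentence, n_types)
            types_here = rng.choice(n_types, size=k, replace=False)
        else:
            types_here = rng.integers(0, n_types,
                                      size=cfg.entities_per_sentence)
        for ti in types_here:
            lab = labels[int(ti)]
            surf = vocabs[lab][int(rng.choice(cfg.vocab_size, p=draw_p[lab]))]
            start = _place(rng, occupied, len(surf), sent_len)
            if start is None:
                n_skipped_placements += 1
                continue
            end = start + len(surf)
            chars[start:end] = list(surf)
            occupied.append((start, end))
            entities.append(EntitySpan(lab, start, end, surf))

        text = "".join(chars)
        entities.sort(key=lambda e: (e.start, e.end, e.label))
        sentences.append(AnnotatedSentence(id=f"synth-{si}", text=text,
                                           entities=tuple(entities)))

    corpus = Corpus(sentences=sentences, schema=cfg.schema)
    lf_rows = low_frequency_analysis(corpus)
    manifest = {
        "n_sentences": cfg.n_sentences,
        "seed": cfg.seed,
        "nested_sentences": n_nested,
        "nested_fraction": n_nested / cfg.n_sentences if cfg.n_sentences else 0.0,
        "skipped_placements": n_skipped_placements,
        "powerlaw_exponents": {lab: exponents[lab] for lab in labels},
        "entity_counts": {r.label: r.total for r in lf_rows},
        "low_frequency": {
            r.label: {"low": r.low_frequency, "total": r.total,
                      "proportion_pct": r.proportion_pct}
            for r in lf_rows
        },
    }
    return corpus, manifest


def make_annotator_pair(corpus: Corpus, disagreement_rate: float,
                        seed: int) -> tuple[Corpus, Corpus]:
    """A second annotation pass that disagrees at a controlled rate.

    Each gold span is independently perturbed with the given probability;
    a perturbation is, with equal probability, a one-character boundary
    shift, a label swap, or a deletion. All perturbations destroy the exact
    match, so the expected agreement F1 is computable from the retention
    probability ``1 - rate``.
    """
    if not (0.0 <= disagreement_rate <= 1.0):
        raise ValueError("disagreement_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(corpus.schema.labels)
    out = []
    for s in corpus:
        new_ents = []
        for e in s.entities:
            if rng.random() >= disagreement_rate:
                new_ents.append(e)
                continue
            kind = rng.integers(3)
            if kind == 2:  # deletion
                continue
            if kind == 1 and len(labels) > 1:  # label swap
                others = [l for l in labels if l != e.label]
                lab = others[int(rng.integers(len(others)))]
                new_ents.append(replace(e, label=lab))
                continue
            # boundary shift by one character, keeping the span valid
            moves = []
            if e.start - 1 >= 0:
                moves.append((e.start - 1, e.end))
            if e.start + 1 < e.end:
                moves.append((e.start + 1, e.end))
            if e.end + 1 <= len(s.text):
                moves.append((e.start, e.end + 1))
            if e.end - 1 > e.start:
                moves.append((e.start, e.end - 1))
            if not moves:
                continue  # degenerate: fall back to deletion
            ns, ne = moves[int(rng.integers(len(moves)))]
            new_ents.append(EntitySpan(e.label, ns, ne, s.text[ns:ne]))
        out.append(replace(s, entities=tuple(new_ents)))
    return corpus, Corpus(sentences=out, schema=corpus.schema)
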