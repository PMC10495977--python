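"""Corpus quality and composition statistics.

Two kinds of report: inter-annotator agreement (IAA), measured as
entity-level F1 with one annotator taken as reference, and frequency
statistics per entity type, including the proportion of low-frequency
entities (surface forms seen exactly once within their type) — the quantity
that drives per-type recognition difficulty.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .corpus_io import Corpus


def _round_half_up(x: float) -> int:
    """Round half away from zero (table conventions print e.g. 31.5% -> 32%)."""
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class IaaReport:
    """Agreement between two annotators on the same sentences, as exact-match F1.

    ``per_type`` maps label -> (tp, fp, fn, P, R, F1); overall numbers are
    micro-averaged (counts pooled over types). Metrics are percentages.
    """

    per_type: dict[str, tuple[int, int, int, float, float, float]]
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _prf_pct(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    # Same 0/0 conventions as evaluation.prf; duplicated here to keep the
    # module free of a circular import.
    if tp == fp == fn == 0:
        return 100.0, 100.0, 100.0
    p = 100.0 * tp / (tp + fp) if (tp + fp) else 0.0
    r = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def compute_iaa(ref: Corpus, other: Corpus) -> IaaReport:
    """Exact-match (label, start, end) agreement between two annotation passes.

    Treats ``ref`` as the reference and ``other`` as the candidate; since
    matched spans are symmetric and FP/FN swap roles, F1 is invariant under
    exchanging the arguments.
    """
    ref_by_id = ref.by_id()
    other_by_id = other.by_id()
    missing = sorted(set(ref_by_id) ^ set(other_by_id))
    if missing:
        raise ValueError(f"sentence ids differ between annotators: {missing}")

    labels = list(ref.schema.labels)
    counts = {lab: [0, 0, 0] for lab in labels}  # tp, fp, fn
    for sid, rs in ref_by_id.items():
        gold = Counter(e.key() for e in rs.entities)
        pred = Counter(e.key() for e in other_by_id[sid].entities)
        for key in gold | pred:
            lab = key[0]
            tp = min(gold[key], pred[key])
            counts[lab][0] += tp
            counts[lab][1] += pred[key] - tp
            counts[lab][2] += gold[key] - tp

    per_type = {}
    for lab in labels:
        tp, fp, fn = counts[lab]
        per_type[lab] = (tp, fp, fn, *_prf_pct(tp, fp, fn))
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    p, r, f1 = _prf_pct(tp, fp, fn)
    return IaaReport(per_type=per_type, tp=tp, fp=fp, fn=fn,
                     precision=p, recall=r, f1=f1)


def entity_counts(corpus: Corpus) -> dict[str, int]:
    """Number of entity mentions per type (sums to total mentions)."""
    counts = {lab: 0 for lab in corpus.schema.labels}
    for s in corpus:
        for e in s.entities:
            counts[e.label] += 1
    return counts


def surface_frequency_table(corpus: Corpus) -> dict[str, Counter]:
    """Per type: surface form -> number of mentions with that surface."""
    table: dict[str, Counter] = {lab: Counter() for lab in corpus.schema.labels}
    for s in corpus:
        for e in s.entities:
            table[e.label][e.surface] += 1
    return table


@dataclass(frozen=True)
class LowFrequencyRow:
    label: str
    low_frequency: int  # distinct surfaces occurring exactly once in the type
    total: int          # total mentions of the type
    proportion_pct: int | None  # whole percent; None when the type is empty


def low_frequency_analysis(corpus: Corpus) -> list[LowFrequencyRow]:
    """Low-frequency entity statistics per type.

    A low-frequency entity is a surface form whose mention count within its
    type is exactly 1. The proportion is low-frequency count / total
    mentions, as a whole percent (half rounded up). Empty types report
    ``None``, not 0.
    """
    table = surface_frequency_table(corpus)
    rows = []
    for lab in corpus.schema.labels:
        freq = table[lab]
        low = sum(1 for c in freq.values() if c == 1)
        total = sum(freq.values())
        rows.append(LowFrequencyRow(
            label=lab,
            low_frequency=low,
            total=total,
            proportion_pct=(low_frequency_proportion(low, total)
                            if total else None),
        ))
    return rows


def low_frequency_proportion(low: int, total: int) -> int:
    """Whole-percent proportion of low-frequency entities (half rounded up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return _round_half_up(100.0 * low / total)
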