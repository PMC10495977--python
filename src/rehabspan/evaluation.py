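"""Entity-level scoring, per-type reports, and the cross-validation harness.

A predicted span counts as a true positive only on exact match of (label,
start, end) against gold. Precision, recall and F1 follow the usual
definitions

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)

reported as percentages. Overall rows are micro-averages (counts pooled
over types before computing P/R/F1); per-type rows use each type's own
counts. Degenerate 0/0 cases: a ratio with zero denominator is 0 when the
opposite error count is nonzero, and a sentence set where both gold and
prediction are empty scores P = R = F1 = 100 by convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus, kfold_split

# re-exported baseline decoder so scoring and baseline live behind one surface
from .baseline import softmax_baseline_decode  # noqa: F401


@dataclass
class MetricCounts:
    """Exact-match TP/FP/FN per entity type; overall = per-type sums."""

    per_type: dict[str, tuple[int, int, int]]

    @property
    def tp(self) -> int:
        return sum(c[0] for c in self.per_type.values())

    @property
    def fp(self) -> int:
        return sum(c[1] for c in self.per_type.values())

    @property
    def fn(self) -> int:
        return sum(c[2] for c in self.per_type.values())


@dataclass
class MetricRow:
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def rounded(self) -> tuple[float, float, float]:
        return (round(self.precision, 2), round(self.recall, 2),
                round(self.f1, 2))


@dataclass
class MetricReport:
    """Per-type and micro-averaged P/R/F1 (percent; display rounds to 2 dp)."""

    per_type: dict[str, MetricRow]
    micro: MetricRow


def score_entities(gold: Corpus, predicted: Corpus) -> MetricCounts:
    """Exact-match span counts over sentences aligned by id."""
    gold_by_id = gold.by_id()
    pred_by_id = predicted.by_id()
    missing = sorted(set(gold_by_id) ^ set(pred_by_id))
    if missing:
        raise ValueError(f"sentence ids differ between corpora: {missing}")
    counts = {lab: [0, 0, 0] for lab in gold.schema.labels}
    for sid, gs in gold_by_id.items():
        g = Counter(e.key() for e in gs.entities)
        p = Counter(e.key() for e in pred_by_id[sid].entities)
        for key in g | p:
            tp = min(g[key], p[key])
            counts[key[0]][0] += tp
            counts[key[0]][1] += p[key] - tp
            counts[key[0]][2] += g[key] - tp
    return MetricCounts(per_type={lab: tuple(c) for lab, c in counts.items()})


def _row(tp: int, fp: int, fn: int) -> MetricRow:
    if tp == fp == fn == 0:
        return MetricRow(100.0, 100.0, 100.0, 0, 0, 0)
    p = 100.0 * tp / (tp + fp) if (tp + fp) else 0.0
    r = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    f1 = f1_from_pr(p, r, digits=None)
    return MetricRow(p, r, f1, tp, fp, fn)


def f1_from_pr(p: float, r: float, digits: int | None = 2) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    f1 = 2.0 * p * r / (p + r) if (p + r) else 0.0
    return round(f1, digits) if digits is not None else f1


def prf(counts: MetricCounts) -> MetricReport:
    """Per-type and micro P/R/F1 from exact-match counts."""
    per_type = {lab: _row(*c) for lab, c in counts.per_type.items()}
    micro = _row(counts.tp, counts.fp, counts.fn)
    return MetricReport(per_type=per_type, micro=micro)


def evaluate(gold: Corpus, predicted: Corpus) -> MetricReport:
    return prf(score_entities(gold, predicted))


@dataclass
class CrossValResult:
    folds: list[MetricReport]
    mean_f1: float
    sd_f1: float
    mean_precision: float
    mean_recall: float


def crossvalidate(corpus: Corpus, k: int, encoder_factory, cfg,
                  seed: int) -> CrossValResult:
    """k-fold cross-validation of the span model.

    ``encoder_factory(train_corpus) -> encoder`` builds a fresh encoder per
    fold (so vocabulary and initialisation never leak across folds); ``cfg``
    is the :class:`~rehabspan.training.TrainConfig` used for every fold.
    Fold assignment and training are deterministic in ``seed``.
    """
    from .training import train  # local import: training does not need us

    folds = kfold_split(corpus, k, seed)
    reports = []
    for fi, (tr, te) in enumerate(folds):
        try:
            model, _ = train(tr, encoder_factory(tr), cfg)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fi}") from exc
        reports.append(evaluate(te, model.predict_corpus(te)))
    f1s = [r.micro.f1 for r in reports]
    return CrossValResult(
        folds=reports,
        mean_f1=float(np.mean(f1s)),
        sd_f1=float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
        mean_precision=float(np.mean([r.micro.precision for r in reports])),
        mean_recall=float(np.mean([r.micro.recall for r in reports])),
    )


def report_text(report: MetricReport, title: str = "entity scores") -> str:
    """Aligned-column text rendering of a metric report."""
    width = max([len(lab) for lab in report.per_type] + [len("micro avg")])
    lines = [title,
             f"{'':{width}}  {'P':>7} {'R':>7} {'F1':>7} {'TP':>5} {'FP':>5} {'FN':>5}"]
    for lab, row in report.per_type.items():
        p, r, f1 = row.rounded()
        lines.append(f"{lab:{width}}  {p:7.2f} {r:7.2f} {f1:7.2f} "
                     f"{row.tp:5d} {row.fp:5d} {row.fn:5d}")
    m = report.micro
    p, r, f1 = m.rounded()
    lines.append(f"{'micro avg':{width}}  {p:7.2f} {r:7.2f} {f1:7.2f} "
                 f"{m.tp:5d} {m.fp:5d} {m.fn:5d}")
    return "\n".join(lines)


def report_json(report: MetricReport) -> dict:
    def row(r: MetricRow) -> dict:
        p, rc, f1 = r.rounded()
        return {"precision": p, "recall": rc, "f1": f1,
                "tp": r.tp, "fp": r.fp, "fn": r.fn}
    return {"per_type": {lab: row(r) for lab, r in report.per_type.items()},
            "micro": row(report.micro), "averaging": "micro"}
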