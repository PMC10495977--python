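"""Span-annotated corpus I/O, validation, BIO conversion, and data splits.

A corpus is a list of sentences, each carrying typed character-offset entity
spans. Offsets are 0-based, half-open on the raw sentence string, so
``text[start:end]`` is the entity surface. The on-disk format is a small
UTF-8 JSON dialect::

    {"schema": ["body", ...],
     "sentences": [{"id": "s1", "text": "...",
                    "entities": [{"label": "body", "start": 2, "end": 4,
                                  "surface": "..."}]}]}

BIO files use one character + tab + tag per line, with a blank line between
sentences. BIO cannot express nested or overlapping spans; conversion is
lossy and signals dropped spans through warnings rather than errors.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: The six-category rehabilitation-medicine entity schema used throughout:
#: four categories specific to rehabilitation plus two shared with clinical
#: medicine.
DEFAULT_LABELS = (
    "dysfunction and performance",
    "rehabilitation assessment",
    "rehabilitation methods",
    "rehabilitation equipment",
    "body",
    "drugs",
)


class CorpusValidationError(ValueError):
    """A corpus violated a structural invariant; message names the span."""


@dataclass(frozen=True)
class EntityTypeSchema:
    """Ordered, stable list of entity-type names."""

    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise CorpusValidationError("schema must have at least one label")
        if len(set(labels)) != len(labels):
            raise CorpusValidationError("schema labels must be unique")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EntitySpan:
    """One typed entity mention: half-open character span plus its surface."""

    label: str
    start: int
    end: int
    surface: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(
                f"span ({self.start},{self.end},{self.label!r}): "
                f"need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "EntitySpan") -> bool:
        """Strict containment of ``other`` inside this span."""
        return (self.start <= other.start and other.end <= self.end
                and self.length > other.length)

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def key(self) -> tuple[str, int, int]:
        return (self.label, self.start, self.end)


@dataclass(frozen=True)
class AnnotatedSentence:
    """Sentence text plus its entity spans; the unit of corpora and predictions."""

    id: str
    text: str
    entities: tuple[EntitySpan, ...] = ()
    #: annotation provenance, "manual" for human labels, "model" for
    #: self-training pseudo-labels
    source: str = "manual"

    def __post_init__(self):
        object.__setattr__(self, "entities", tuple(self.entities))

    def validate(self, schema: EntityTypeSchema) -> None:
        for sp in self.entities:
            if sp.end > len(self.text):
                raise CorpusValidationError(
                    f"sentence {self.id!r}: span ({sp.start},{sp.end},"
                    f"{sp.label!r}) exceeds text length {len(self.text)}"
                )
            slice_ = self.text[sp.start:sp.end]
            if sp.surface != slice_:
                raise CorpusValidationError(
                    f"sentence {self.id!r}: span ({sp.start},{sp.end}) surface "
                    f"{sp.surface!r} != text slice {slice_!r}"
                )
            if sp.label not in schema:
                raise CorpusValidationError(
                    f"sentence {self.id!r}: unknown label {sp.label!r}"
                )


@dataclass
class Corpus:
    """A validated collection of annotated sentences under one schema."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)
    schema: EntityTypeSchema = field(default_factory=EntityTypeSchema)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.sentences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate sentence ids: {dupes}")
        for s in self.sentences:
            s.validate(self.schema)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def by_id(self) -> dict[str, AnnotatedSentence]:
        return {s.id: s for s in self.sentences}

    def total_entities(self) -> int:
        return sum(len(s.entities) for s in self.sentences)


def check_annotation_rules(corpus: Corpus) -> list[str]:
    """Soft annotation-rule checks; returns warning strings (never raises).

    Implements the corpus annotation guidelines as advisory checks:
    overlapping spans within a sentence, and spans whose surface is entirely
    Latin script (full foreign-language terms are conventionally left
    unmarked). These warn rather than fail because nested annotation is a
    deliberate feature of span-based corpora.
    """
    msgs = []
    for s in corpus:
        ents = sorted(s.entities, key=lambda e: (e.start, -e.end))
        for a_i, a in enumerate(ents):
            for b in ents[a_i + 1:]:
                if b.start >= a.end:
                    break
                if a.overlaps(b):
                    msgs.append(
                        f"sentence {s.id!r}: overlapping spans "
                        f"{a.key()} and {b.key()}"
                    )
            if a.surface and all(
                ("a" <= c.lower() <= "z") for c in a.surface
            ):
                msgs.append(
                    f"sentence {s.id!r}: all-Latin surface {a.surface!r} "
                    f"at {a.key()}"
                )
    for m in msgs:
        logger.warning(m)
    return msgs


# ---------------------------------------------------------------------------
# JSON dialect

def read_json_corpus(path, schema: EntityTypeSchema | None = None) -> Corpus:
    """Read and validate a JSON corpus file.

    If ``schema`` is None the schema stored in the file is used; otherwise
    the file's labels must match the given schema.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CorpusValidationError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(raw, dict) or "sentences" not in raw:
        raise CorpusValidationError(f"{path}: expected object with 'sentences'")
    file_schema = EntityTypeSchema(tuple(raw.get("schema", DEFAULT_LABELS)))
    if schema is not None and tuple(schema.labels) != file_schema.labels:
        raise CorpusValidationError(
            f"{path}: file schema {file_schema.labels} does not match "
            f"expected {tuple(schema.labels)}"
        )
    sentences = []
    for rec in raw["sentences"]:
        ents = tuple(
            EntitySpan(e["label"], int(e["start"]), int(e["end"]), e["surface"])
            for e in rec.get("entities", ())
        )
        sentences.append(
            AnnotatedSentence(
                id=str(rec["id"]),
                text=rec["text"],
                entities=ents,
                source=rec.get("source", "manual"),
            )
        )
    return Corpus(sentences=sentences, schema=file_schema)


def write_json_corpus(corpus: Corpus, path) -> None:
    """Write the corpus in the JSON dialect; output is byte-stable."""
    payload = {
        "schema": list(corpus.schema.labels),
        "sentences": [
            {
                "id": s.id,
                "text": s.text,
                "source": s.source,
                "entities": [
                    {"label": e.label, "start": e.start, "end": e.end,
                     "surface": e.surface}
                    for e in s.entities
                ],
            }
            for s in corpus
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# BIO conversion

class DroppedSpanWarning(UserWarning):
    """A span could not be encoded in BIO (nesting/overlap) and was dropped."""


def _select_flat_spans(entities) -> tuple[list[EntitySpan], list[EntitySpan]]:
    """Maximal non-overlapping subset: earlier start first, then longer span."""
    ordered = sorted(entities, key=lambda e: (e.start, -(e.end - e.start)))
    kept: list[EntitySpan] = []
    dropped: list[EntitySpan] = []
    for sp in ordered:
        if any(sp.overlaps(k) for k in kept):
            dropped.append(sp)
        else:
            kept.append(sp)
    return kept, dropped


def to_bio(sentence: AnnotatedSentence) -> list[str]:
    """Per-character BIO tags; nested/overlapping spans are dropped with warnings.

    Among overlapping candidates the earlier-starting span wins, ties broken
    toward the longer span, so outermost spans survive and inner ones are
    reported via :class:`DroppedSpanWarning`.
    """
    tags = ["O"] * len(sentence.text)
    kept, dropped = _select_flat_spans(sentence.entities)
    for sp in kept:
        tags[sp.start] = f"B-{sp.label}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.label}"
    for sp in dropped:
        warnings.warn(
            f"sentence {sentence.id!r}: span {sp.key()} dropped in BIO "
            f"encoding (nesting/overlap)",
            DroppedSpanWarning,
            stacklevel=2,
        )
    return tags


def from_bio(chars, tags, schema: EntityTypeSchema,
             sentence_id: str = "bio") -> AnnotatedSentence:
    """Inverse of :func:`to_bio` for flat annotations.

    Orphan ``I-`` tags (no preceding ``B-``/``I-`` of the same label) are
    repaired to ``B-`` and logged, so third-party BIO files with minor tag
    glitches still import.
    """
    chars = list(chars)
    tags = list(tags)
    if len(chars) != len(tags):
        raise ValueError(
            f"length mismatch: {len(chars)} characters vs {len(tags)} tags"
        )
    text = "".join(chars)
    entities: list[EntitySpan] = []
    cur_label, cur_start = None, None

    def close(end):
        nonlocal cur_label, cur_start
        if cur_label is not None:
            entities.append(
                EntitySpan(cur_label, cur_start, end, text[cur_start:end])
            )
        cur_label, cur_start = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i)
            continue
        if "-" not in tag or tag.split("-", 1)[0] not in ("B", "I"):
            raise ValueError(f"malformed BIO tag {tag!r} at position {i}")
        prefix, label = tag.split("-", 1)
        if label not in schema:
            raise ValueError(f"unknown label {label!r} in tag at position {i}")
        if prefix == "I" and cur_label == label:
            continue  # extend current entity
        if prefix == "I":
            logger.warning(
                "sentence %r: orphan I-%s at position %d repaired to B-%s",
                sentence_id, label, i, label,
            )
        close(i)
        cur_label, cur_start = label, i
    close(len(tags))
    sent = AnnotatedSentence(id=sentence_id, text=text, entities=tuple(entities))
    sent.validate(schema)
    return sent


def read_bio_file(path, schema: EntityTypeSchema) -> Corpus:
    """Read a BIO file (char<TAB>tag per line, blank line between sentences)."""
    sentences = []
    chars: list[str] = []
    tags: list[str] = []

    def flush():
        if chars:
            sid = f"bio-{len(sentences)}"
            sentences.append(
                replace(from_bio(chars, tags, schema, sentence_id=sid))
            )
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            ch, _, tag = line.partition("\t")
            chars.append(ch)
            tags.append(tag)
    flush()
    return Corpus(sentences=sentences, schema=schema)


def write_bio_file(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus:
            for ch, tag in zip(s.text, to_bio(s)):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Splits

def split_corpus(corpus: Corpus, train_fraction: float,
                 seed: int) -> tuple[Corpus, Corpus]:
    """Deterministic random train/test partition.

    The train size is ``round(n * train_fraction)`` (e.g. the conventional
    9:1 split of 2,500 sentences gives 2,250/250).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 sentences to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    mk = lambda idx: Corpus(
        sentences=[corpus.sentences[i] for i in idx], schema=corpus.schema
    )
    return mk(train_idx), mk(test_idx)


def kfold_split(corpus: Corpus, k: int, seed: int) -> list[tuple[Corpus, Corpus]]:
    """k deterministic (train, test) pairs; test folds partition the corpus.

    Fold sizes differ by at most one: the first ``n mod k`` folds take the
    extra sentence.
    """
    n = len(corpus)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds corpus size {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n).tolist()
    base, extra = divmod(n, k)
    folds = []
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        test_idx = set(perm[pos:pos + size])
        pos += size
        train = [s for i, s in enumerate(corpus.sentences) if i not in test_idx]
        test = [s for i, s in enumerate(corpus.sentences) if i in test_idx]
        folds.append(
            (Corpus(sentences=train, schema=corpus.schema),
             Corpus(sentences=test, schema=corpus.schema))
        )
    return folds
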