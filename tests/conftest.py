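import numpy as np
import pytest

import rehabspan as rs
from rehabspan.corpus_io import (AnnotatedSentence, Corpus, EntitySpan,
                                 EntityTypeSchema)
from rehabspan.span_model import CategoryHead, SpanHead


@pytest.fixture(scope="session")
def schema():
    return EntityTypeSchema()


@pytest.fixture(scope="session")
def abc_schema():
    return EntityTypeSchema(("a", "b", "c"))


@pytest.fixture
def tiny_corpus(schema):
    s1 = AnnotatedSentence(
        "s1", "患者肢体麻木",
        (EntitySpan("body", 2, 4, "肢体"),
         EntitySpan("dysfunction and performance", 2, 6, "肢体麻木")))
    s2 = AnnotatedSentence(
        "s2", "服用阿司匹林后进行康复训练",
        (EntitySpan("drugs", 2, 6, "阿司匹林"),
         EntitySpan("rehabilitation methods", 9, 13, "康复训练")))
    s3 = AnnotatedSentence("s3", "无异常", ())
    return Corpus(sentences=[s1, s2, s3], schema=schema)


@pytest.fixture(scope="session")
def synth_corpus():
    corpus, manifest = rs.generate(rs.SynthConfig(n_sentences=200, seed=7))
    return corpus, manifest


@pytest.fixture(scope="session")
def overfit_run():
    """Train the span model to convergence on a separable synthetic corpus.

    Session-scoped because several suites (training behaviour, evaluation,
    self-training, acceptance) reuse the same converged model.
    """
    corpus, _ = rs.generate(rs.SynthConfig(n_sentences=200, seed=7,
                                           nesting_rate=0.1))
    encoder = rs.TinyEncoder.from_corpus(corpus, d=32, seed=3)
    cfg = rs.TrainConfig(learning_rate=0.02, epochs=30, batch_size=8,
                         seed=3, warmup_proportion=0.15)
    model, log = rs.train(corpus, encoder, cfg, max_span_len=12)
    report = rs.evaluate(corpus, model.predict_corpus(corpus))
    return corpus, model, log, report


def forcing_head(schema: EntityTypeSchema, n: int,
                 spans_by_label: dict[str, list[tuple[int, int]]]) -> SpanHead:
    """Span head whose scores force exactly the given gold spans on E = I_n.

    Spans are (start, end) half-open. Boundary logits are ±10 at the gold
    start/end positions; the matcher weight is uniformly positive, so every
    admissible candidate pair within a category is accepted.
    """
    heads = {}
    for lab in schema.labels:
        T_start = np.zeros((n, 2))
        T_end = np.zeros((n, 2))
        T_start[:, 1] = -10.0
        T_end[:, 1] = -10.0
        for (i, end) in spans_by_label.get(lab, []):
            T_start[i, 1] = 10.0
            T_end[end - 1, 1] = 10.0
        heads[lab] = CategoryHead(T_start=T_start, T_end=T_end,
                                  U=np.zeros((2, n)), m=np.ones(2 * n))
    return SpanHead(schema=schema, d=n, heads=heads)
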