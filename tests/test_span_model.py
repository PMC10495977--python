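import math

import numpy as np
import pytest

from rehabspan.corpus_io import AnnotatedSentence, EntitySpan, EntityTypeSchema
from rehabspan.span_model import (CategoryHead, LossConfig, SpanHead,
                                  SpanPredictions, build_targets,
                                  compute_loss, decode_entities,
                                  extract_indices, forward, forward_backward,
                                  indicator_from_labels, match_pair,
                                  predict_end, predict_start, load_head,
                                  save_head, start_indicator)
from conftest import forcing_head


def zero_head(d):
    return CategoryHead(T_start=np.zeros((d, 2)), T_end=np.zeros((d, 2)),
                        U=np.zeros((2, d)), m=np.zeros(2 * d))


class TestBoundaryPrediction:
    def test_zero_projection_gives_uniform_rows(self):
        E = np.random.default_rng(0).normal(size=(5, 4))
        P = predict_start(E, zero_head(4))
        assert np.allclose(P, 0.5)

    def test_known_logits(self):
        # E row [1, 0] against columns producing logits (10, 0)
        E = np.array([[1.0, 0.0]])
        head = zero_head(2)
        head.T_start = np.array([[10.0, 0.0], [0.0, 0.0]])
        P = predict_start(E, head)
        assert P[0, 0] == pytest.approx(0.9999546, abs=1e-7)
        assert P[0, 1] == pytest.approx(0.0000454, abs=1e-7)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(7, 6)) * 5
        head = CategoryHead.init(6, rng, scale=1.0)
        for P in (predict_start(E, head),
                  predict_end(E, start_indicator(predict_start(E, head)), head)):
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
            assert (P >= 0).all() and (P <= 1).all()

    def test_non_finite_input_rejected(self):
        E = np.full((2, 3), np.nan)
        with pytest.raises(FloatingPointError):
            predict_start(E, zero_head(3))

    def test_end_indicator_is_row_local(self):
        rng = np.random.default_rng(2)
        E = rng.normal(size=(6, 4))
        head = CategoryHead.init(4, rng, scale=0.5)
        ind = indicator_from_labels(np.zeros(6))
        ind_flipped = indicator_from_labels(
            np.array([0, 0, 1, 0, 0, 0], dtype=float))
        P1 = predict_end(E, ind, head)
        P2 = predict_end(E, ind_flipped, head)
        changed = np.flatnonzero(np.abs(P1 - P2).max(axis=1) > 1e-12)
        assert changed.tolist() == [2]

    def test_gold_indicator_shifts_logits_by_projected_embedding(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(4, 5))
        head = CategoryHead.init(5, rng, scale=0.5)
        y = np.array([0, 1, 0, 0], dtype=float)
        with_ind = (E + indicator_from_labels(y) @ head.U) @ head.T_end
        base = (E + indicator_from_labels(np.zeros(4)) @ head.U) @ head.T_end
        expected_delta = (head.U[1] - head.U[0]) @ head.T_end
        assert np.allclose((with_ind - base)[1], expected_delta)
        assert np.allclose((with_ind - base)[[0, 2, 3]], 0.0)

    def test_indicator_shape_checked(self):
        with pytest.raises(ValueError, match="indicator"):
            predict_end(np.zeros((3, 2)), np.zeros((2, 2)), zero_head(2))


class TestIndexExtraction:
    def test_argmax_rule(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert extract_indices(P) == frozenset({1})

    def test_all_negative_rows_empty(self):
        assert extract_indices(np.tile([1.0, 0.0], (4, 1))) == frozenset()

    def test_tie_breaks_to_non_entity(self):
        P = np.array([[0.5, 0.5], [0.4, 0.6]])
        assert extract_indices(P) == frozenset({1})
        assert start_indicator(P)[0].tolist() == [1.0, 0.0]


class TestPairMatching:
    def test_zero_weights_give_half(self):
        E = np.random.default_rng(0).normal(size=(4, 3))
        assert match_pair(E, 0, 3, zero_head(3)) == pytest.approx(0.5)

    def test_known_logit(self):
        E = np.array([[1.0], [1.0]])
        head = zero_head(1)
        head.m = np.array([1.5, 0.5])  # m·concat = 2.0
        assert match_pair(E, 0, 1, head) == pytest.approx(0.8807971, abs=1e-7)

    def test_monotone_in_logit(self):
        E = np.array([[1.0], [1.0]])
        probs = []
        for z in (-2.0, 0.0, 1.0, 3.0):
            head = zero_head(1)
            head.m = np.array([z, 0.0])
            probs.append(match_pair(E, 0, 1, head))
        assert probs == sorted(probs)

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            match_pair(np.zeros((3, 2)), 2, 1, zero_head(2))


class TestDecoding:
    def test_single_admissible_pair(self, abc_schema):
        head = forcing_head(abc_schema, 6, {"a": [(1, 4)]})
        spans = decode_entities(np.eye(6), head, text="甲乙丙丁戊己")
        assert [s.key() for s in spans] == [("a", 1, 4)]
        assert spans[0].surface == "乙丙丁"

    def test_overlapping_pairs_all_retained(self, abc_schema):
        # starts {1,5}, ends at 3 and 7 (0-based, inclusive): all i<=j pairs
        head = forcing_head(abc_schema, 9, {"a": [(1, 4), (5, 8)]})
        spans = decode_entities(np.eye(9), head)
        assert {s.key() for s in spans} == \
            {("a", 1, 4), ("a", 1, 8), ("a", 5, 8)}

    def test_ends_before_starts_yield_nothing(self, abc_schema):
        heads = forcing_head(abc_schema, 6, {})
        h = heads.heads["a"]
        h.T_start[4, 1] = 10.0   # start candidate at 4
        h.T_end[1, 1] = 10.0     # end candidate at 1 < 4
        assert decode_entities(np.eye(6), heads) == []

    def test_max_span_len_filters_pairs(self, abc_schema):
        head = forcing_head(abc_schema, 9, {"a": [(1, 4), (5, 8)]})
        spans = decode_entities(np.eye(9), head, max_span_len=4)
        assert {s.key() for s in spans} == {("a", 1, 4), ("a", 5, 8)}

    def test_threshold_filters_pairs(self, abc_schema):
        head = forcing_head(abc_schema, 6, {"a": [(1, 4)]})
        assert decode_entities(np.eye(6), head, threshold=0.9) == []

    def test_cross_category_nesting_decodable(self, abc_schema):
        # an inner span of another category strictly inside an outer span
        head = forcing_head(abc_schema, 8, {"a": [(0, 6)], "b": [(2, 5)]})
        spans = decode_entities(np.eye(8), head)
        assert {s.key() for s in spans} == {("a", 0, 6), ("b", 2, 5)}

    def test_matches_brute_force_oracle_on_random_instances(self, abc_schema):
        # independent oracle: enumerate every (category, i, j) triple and
        # re-apply the argmax and threshold rules from raw probabilities
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(2, 13))
            d = int(rng.integers(2, 6))
            E = rng.normal(size=(n, d)) * 2
            head = SpanHead(schema=abc_schema, d=d,
                            heads={lab: CategoryHead.init(d, rng, scale=1.5)
                                   for lab in abc_schema.labels})
            max_len = int(rng.integers(1, n + 2))
            got = {s.key() for s in decode_entities(E, head,
                                                    max_span_len=max_len)}
            expected = set()
            for lab in abc_schema.labels:
                h = head.heads[lab]
                Ps = predict_start(E, h)
                Pe = predict_end(E, start_indicator(Ps), h)
                for i in range(n):
                    for j in range(n):
                        if not (i <= j and j - i < max_len):
                            continue
                        if Ps[i, 1] <= Ps[i, 0] or Pe[j, 1] <= Pe[j, 0]:
                            continue
                        z = float(h.m @ np.concatenate([E[i], E[j]]))
                        if 1.0 / (1.0 + math.exp(-z)) > 0.5:
                            expected.add((lab, i, j + 1))
            assert got == expected


class TestLoss:
    def perfect_predictions(self, tgt):
        p_start, p_end, p_pairs = {}, {}, {}
        for lab, ct in tgt.per_category.items():
            n = tgt.n
            ps = np.zeros((n, 2))
            ps[np.arange(n), ct.y_start.astype(int)] = 1.0
            pe = np.zeros((n, 2))
            pe[np.arange(n), ct.y_end.astype(int)] = 1.0
            p_start[lab], p_end[lab] = ps, pe
            p_pairs[lab] = np.array([float(y) for _, _, y in ct.pairs])
        return SpanPredictions(p_start, p_end, p_pairs)

    @pytest.fixture
    def targets(self, abc_schema):
        text = "甲乙丙丁戊己"
        sent = AnnotatedSentence("s", text, (
            EntitySpan("a", 0, 3, text[0:3]),
            EntitySpan("a", 4, 6, text[4:6]),
            EntitySpan("b", 1, 2, text[1:2])))
        return build_targets(sent, abc_schema, seed=0)

    def test_zero_loss_at_perfect_prediction(self, targets):
        total, comps = compute_loss(self.perfect_predictions(targets),
                                    targets, LossConfig())
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_uniform_boundary_rows_cost_ln2(self, targets):
        pred = self.perfect_predictions(targets)
        for lab in pred.p_start:
            pred.p_start[lab] = np.full_like(pred.p_start[lab], 0.5)
        total, comps = compute_loss(pred, targets,
                                    LossConfig(alpha=1, beta=0, gamma=0))
        assert total == pytest.approx(math.log(2), abs=1e-9)
        assert comps["start"] == pytest.approx(math.log(2), abs=1e-9)

    def test_total_linear_in_weights(self, targets, abc_schema):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(targets.n, 4))
        head = SpanHead.init(abc_schema, 4, rng)
        pred = forward(E, head, targets)
        _, comps = compute_loss(pred, targets, LossConfig())
        for a, b, g in [(1, 1, 1), (2, 0.5, 0), (0, 0, 3)]:
            total, _ = compute_loss(pred, targets, LossConfig(a, b, g))
            assert total == pytest.approx(
                a * comps["start"] + b * comps["end"] + g * comps["span"])

    def test_empty_pair_sample_warns(self, abc_schema):
        sent = AnnotatedSentence("s", "甲乙丙", ())
        tgt = build_targets(sent, abc_schema, seed=0)
        pred = self.perfect_predictions(tgt)
        with pytest.warns(UserWarning, match="empty candidate-pair"):
            total, comps = compute_loss(pred, tgt, LossConfig())
        assert comps["span"] == 0.0

    def test_gradient_step_decreases_loss(self, targets, abc_schema):
        rng = np.random.default_rng(6)
        E = rng.normal(size=(targets.n, 4))
        head = SpanHead.init(abc_schema, 4, rng)
        cfg = LossConfig()
        loss0, _, grads, _ = forward_backward(E, head, targets, cfg)
        lr = 0.1
        for lab in abc_schema.labels:
            h = head.heads[lab]
            h.T_start -= lr * grads[lab]["T_start"]
            h.T_end -= lr * grads[lab]["T_end"]
            h.U -= lr * grads[lab]["U"]
            h.m -= lr * grads[lab]["m"]
        loss1, _, _, _ = forward_backward(E, head, targets, cfg)
        assert loss1 < loss0

    def test_loss_nonnegative_on_random_inputs(self, targets, abc_schema):
        rng = np.random.default_rng(7)
        for _ in range(10):
            E = rng.normal(size=(targets.n, 3)) * 3
            head = SpanHead.init(abc_schema, 3, rng)
            pred = forward(E, head, targets)
            total, _ = compute_loss(pred, targets, LossConfig())
            assert total >= 0.0


class TestTargetsAndCheckpoint:
    def test_negative_pairs_are_start_end_cross_products(self, abc_schema):
        text = "甲乙丙丁戊己庚辛"
        sent = AnnotatedSentence("s", text, (
            EntitySpan("a", 0, 3, text[0:3]),
            EntitySpan("a", 5, 8, text[5:8])))
        tgt = build_targets(sent, abc_schema, seed=0)
        pairs = set((i, j, y) for i, j, y in tgt.per_category["a"].pairs)
        assert (0, 2, 1) in pairs and (5, 7, 1) in pairs
        assert (0, 7, 0) in pairs          # crossing negative
        assert not any(p[:2] == (5, 2) for p in pairs)  # i > j excluded

    def test_pair_cap_is_deterministic(self, abc_schema):
        text = "甲乙丙丁戊己庚辛壬癸" * 2
        ents = tuple(EntitySpan("a", i, i + 2, text[i:i + 2])
                     for i in range(0, 18, 3))
        sent = AnnotatedSentence("s", text, ents)
        t1 = build_targets(sent, abc_schema, max_pairs=10, seed=4)
        t2 = build_targets(sent, abc_schema, max_pairs=10, seed=4)
        assert t1.per_category["a"].pairs == t2.per_category["a"].pairs
        assert len(t1.per_category["a"].pairs) == 10

    def test_head_checkpoint_roundtrip(self, abc_schema, tmp_path):
        rng = np.random.default_rng(8)
        head = SpanHead.init(abc_schema, 5, rng)
        save_head(head, tmp_path)
        back = load_head(tmp_path)
        assert back.schema.labels == abc_schema.labels
        for lab in abc_schema.labels:
            for name, arr in head.heads[lab].arrays().items():
                assert np.array_equal(arr, back.heads[lab].arrays()[name])
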