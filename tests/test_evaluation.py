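"""Strict-match metrics and breakdown analyses."""

import numpy as np
import pytest

from gptriple.evaluation import (
    Metrics,
    OverlapLabel,
    bucket_by_triple_count,
    classify_overlap,
    evaluation_report,
    per_bucket_metrics,
    per_category_metrics,
    per_relation_metrics,
    strict_match,
)
from gptriple.types import EntitySpan, RelationSchema, Triple


def T(sh, st, k, oh, ot):
    return Triple(EntitySpan(sh, st), k, EntitySpan(oh, ot))


A, B, C, D = EntitySpan(0, 1), EntitySpan(3, 4), EntitySpan(6, 7), EntitySpan(9, 9)


class TestStrictMatch:
    def test_identity_prediction_is_perfect(self):
        gold = {"s1": {T(0, 1, 0, 3, 4)}, "s2": {T(0, 0, 1, 2, 3)}}
        m = strict_match(gold, gold)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction(self):
        gold = {"s1": {T(0, 1, 0, 3, 4)}}
        m = strict_match(gold, {"s1": set()})
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_hand_computed_counts(self):
        """4 gold, 3 predicted of which 2 correct: P=2/3, R=1/2, F1=4/7."""
        gold = {"s": {T(0, 1, 0, 3, 4), T(0, 1, 1, 3, 4),
                      T(6, 7, 0, 9, 9), T(0, 0, 2, 6, 7)}}
        pred = {"s": {T(0, 1, 0, 3, 4), T(0, 1, 1, 3, 4), T(5, 5, 0, 9, 9)}}
        m = strict_match(gold, pred)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1 / 2)
        assert m.f1 == pytest.approx(4 / 7)

    def test_span_shift_is_not_a_match(self):
        gold = {"s": {T(0, 2, 0, 4, 5)}}
        pred = {"s": {T(0, 1, 0, 4, 5)}}
        assert strict_match(gold, pred).tp == 0

    def test_relation_mismatch_is_not_a_match(self):
        gold = {"s": {T(0, 2, 0, 4, 5)}}
        pred = {"s": {T(0, 2, 1, 4, 5)}}
        assert strict_match(gold, pred).tp == 0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            strict_match({"s1": set()}, {"s2": set()})

    def test_cross_check_against_sklearn(self, rng):
        """P/R/F1 arithmetic agrees with scikit-learn on indicator vectors
        over the union of observed triples."""
        from sklearn.metrics import precision_recall_fscore_support

        gold, pred = {}, {}
        for i in range(30):
            sid = f"s{i}"
            pool = [T(a, a + 1, k, b, b + 1) for a in (0, 3) for b in (6, 9) for k in (0, 1)]
            gold[sid] = {pool[j] for j in rng.choice(8, size=3, replace=False)}
            pred[sid] = {pool[j] for j in rng.choice(8, size=3, replace=False)}
        universe = sorted({(sid, t) for sid in gold for t in gold[sid] | pred[sid]})
        y_true = [1 if t in gold[sid] else 0 for sid, t in universe]
        y_pred = [1 if t in pred[sid] else 0 for sid, t in universe]
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0
        )
        m = strict_match(gold, pred)
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f1 == pytest.approx(f)


class TestClassifyOverlap:
    def test_single_triple_is_normal(self):
        assert classify_overlap({T(0, 1, 0, 3, 4)}) == {OverlapLabel.NORMAL}

    def test_same_pair_two_relations_is_epo(self):
        ts = {Triple(A, 0, B), Triple(A, 1, B)}
        assert classify_overlap(ts) == {OverlapLabel.EPO}

    def test_one_shared_entity_is_seo(self):
        ts = {Triple(A, 0, B), Triple(A, 0, C)}
        assert classify_overlap(ts) == {OverlapLabel.SEO}

    def test_seo_and_epo_can_cooccur(self):
        ts = {Triple(A, 0, B), Triple(A, 1, B), Triple(A, 0, C)}
        assert classify_overlap(ts) == {OverlapLabel.SEO, OverlapLabel.EPO}

    def test_disjoint_triples_are_normal(self):
        ts = {Triple(A, 0, B), Triple(C, 1, D)}
        assert classify_overlap(ts) == {OverlapLabel.NORMAL}

    def test_permutation_invariant(self):
        ts = [Triple(A, 0, B), Triple(A, 1, C), Triple(C, 0, D)]
        assert classify_overlap(ts) == classify_overlap(list(reversed(ts)))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            classify_overlap(set())


class TestBuckets:
    def test_counting(self):
        gold = {
            "a": {Triple(A, 0, B)},
            "b": {Triple(A, 0, B)},
            "c": {Triple(A, 0, B), Triple(C, 0, D)},
            "d": {Triple(A, k, B) for k in range(5)},
            "e": {Triple(A, k, B) for k in range(7)},
        }
        buckets = bucket_by_triple_count(gold)
        sizes = {k: len(v) for k, v in buckets.items()}
        assert sizes == {"1": 2, "2": 1, "3": 0, "4": 0, ">=5": 2}

    def test_empty_corpus(self):
        assert all(len(v) == 0 for v in bucket_by_triple_count({}).values())

    def test_partition_covers_corpus(self, small_corpus):
        _, examples, _ = small_corpus
        gold = {e.sentence.id: set(e.triples) for e in examples}
        buckets = bucket_by_triple_count(gold)
        assert sum(len(v) for v in buckets.values()) == len(gold)


class TestPerRelation:
    def test_perfect_on_one_relation_only(self):
        schema = RelationSchema(["r0", "r1"])
        gold = {"s": {Triple(A, 0, B), Triple(C, 1, D)}}
        pred = {"s": {Triple(A, 0, B)}}
        per = per_relation_metrics(gold, pred, schema)
        assert per["r0"].f1 == 1.0
        assert per["r1"].f1 == 0.0

    def test_counts_conserve_global(self, rng):
        schema = RelationSchema(["r0", "r1", "r2"])
        gold, pred = {}, {}
        for i in range(25):
            sid = f"s{i}"
            pool = [T(a, a + 1, k, 6, 7) for a in (0, 3) for k in range(3)]
            gold[sid] = {pool[j] for j in rng.choice(6, size=2, replace=False)}
            pred[sid] = {pool[j] for j in rng.choice(6, size=2, replace=False)}
        per = per_relation_metrics(gold, pred, schema)
        total = Metrics(0, 0, 0)
        for m in per.values():
            total = total + m
        g = strict_match(gold, pred)
        assert (total.tp, total.fp, total.fn) == (g.tp, g.fp, g.fn)

    def test_absent_relation_flagged(self):
        schema = RelationSchema(["r0", "r1"])
        gold = {"s": {Triple(A, 0, B)}}
        report = evaluation_report(gold, gold, schema)
        assert report["by_relation"]["r1"]["absent"] is True
        assert report["by_relation"]["r0"]["absent"] is False


class TestReport:
    def test_category_and_bucket_sections(self):
        schema = RelationSchema(["r0", "r1"])
        gold = {
            "n": {Triple(A, 0, B)},
            "epo": {Triple(A, 0, B), Triple(A, 1, B)},
        }
        pred = {"n": {Triple(A, 0, B)}, "epo": {Triple(A, 0, B)}}
        rep = evaluation_report(gold, pred, schema)
        assert rep["by_category"]["Normal"]["f1"] == 1.0
        assert rep["by_category"]["EPO"]["recall"] == pytest.approx(0.5)
        assert rep["by_triple_count"]["1"]["f1"] == 1.0
        assert rep["global"]["tp"] == 2
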