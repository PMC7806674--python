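"""Nearest-neighbor transfer, tie expansion, reliability index, naive baseline."""

from __future__ import annotations

import io

import numpy as np
import pytest

import gotransfer as gt
from gotransfer.errors import ValidationError
from gotransfer.transfer import Hit, _score_hits

from conftest import A, B, C


def knn_oracle(query, store, k, metric):
    """Exhaustive sort, then expand the k-th distance cohort."""
    dist_fn = gt.euclidean if metric == "euclidean" else gt.cosine
    pairs = sorted((dist_fn(query, store[pid]), pid) for pid in store.ids)
    if k >= len(pairs):
        return pairs
    kth = pairs[k - 1][0]
    return [(d, pid) for d, pid in pairs
            if d <= kth or abs(d - kth) <= 1e-9 * max(abs(d), abs(kth), 1e-12)]


class TestNearestNeighbors:
    def test_exact_match_single_hit(self):
        store = gt.EmbeddingStore({"T1": [1.0, 0.0], "T2": [5.0, 5.0]})
        hits = gt.nearest_neighbors(np.array([1.0, 0.0]), store, k=1)
        assert [(h.id, h.distance) for h in hits] == [("T1", 0.0)]

    def test_equidistant_targets_all_returned(self):
        store = gt.EmbeddingStore({
            "T1": [1.0, 0.0], "T2": [-1.0, 0.0], "T3": [0.0, 1.0],
        })
        hits = gt.nearest_neighbors(np.zeros(2), store, k=1)
        assert sorted(h.id for h in hits) == ["T1", "T2", "T3"]
        assert [h.rank for h in hits] == [1, 2, 3]

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_exhaustive_sort_oracle(self, k, metric):
        rng = np.random.default_rng(10 * k + (metric == "cosine"))
        store = gt.EmbeddingStore(
            {f"T{i:03d}": rng.normal(size=32) for i in range(200)}
        )
        for _ in range(5):
            q = rng.normal(size=32)
            hits = gt.nearest_neighbors(q, store, k=k, metric=metric)
            expected = knn_oracle(q, store, k, metric)
            assert [h.id for h in hits] == [pid for _, pid in expected]
            np.testing.assert_allclose([h.distance for h in hits],
                                       [d for d, _ in expected], atol=1e-12)

    def test_exclusion_removes_self_hit(self):
        store = gt.EmbeddingStore({"Q": [0.0, 0.0], "T": [1.0, 0.0]})
        hits = gt.nearest_neighbors(np.zeros(2), store, k=1, exclude={"Q"})
        assert [h.id for h in hits] == ["T"]

    def test_drop_zero_distance_emulates_identity_purge(self):
        store = gt.EmbeddingStore({"T0": [0.0, 0.0], "T1": [2.0, 0.0]})
        hits = gt.nearest_neighbors(np.zeros(2), store, k=1,
                                    drop_zero_distance=True)
        assert [h.id for h in hits] == ["T1"]

    def test_k_larger_than_store_returns_all_with_warning(self, caplog):
        store = gt.EmbeddingStore({"T1": [0.0], "T2": [1.0]})
        with caplog.at_level("WARNING"):
            hits = gt.nearest_neighbors(np.array([0.0]), store, k=5)
        assert len(hits) == 2
        assert "exceeds store size" in caplog.text

    def test_empty_store_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            gt.nearest_neighbors(np.zeros(2), gt.EmbeddingStore({"Q": [0.0, 0.0]}),
                                 k=1, exclude={"Q"})


class TestReliabilityIndex:
    def test_identical_embedding_gives_ri_one(self):
        assert gt.reliability_index([Hit("T", 0.0, 1)], [True], k=1) == 1.0

    def test_half_distance_formula_value(self):
        assert gt.reliability_index([Hit("T", 0.5, 1)], [True], k=1) == \
            pytest.approx(0.5)

    def test_unannotated_hit_contributes_nothing(self):
        hits = [Hit("T1", 0.0, 1), Hit("T2", 1.0, 2)]
        assert gt.reliability_index(hits, [True, False], k=2) == pytest.approx(0.5)

    def test_tie_expansion_clamped_to_one(self):
        hits = [Hit(f"T{i}", 0.0, i + 1) for i in range(3)]
        assert gt.reliability_index(hits, [True] * 3, k=1) == 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            gt.reliability_index([Hit("T", -0.1, 1)], [True], k=1)

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            d = float(rng.uniform(0.01, 5.0))
            closer = gt.reliability_index([Hit("T", d * 0.9, 1)], [True], k=1)
            farther = gt.reliability_index([Hit("T", d, 1)], [True], k=1)
            assert closer >= farther


class TestTransfer:
    def _propagated(self, ont, rows):
        ann = gt.AnnotationSet()
        for protein, ns, term in rows:
            ann.add(protein, ns, term, "IDA")
        return gt.propagate_annotations(ann, ont)

    def test_identity_transfer_reproduces_hit_annotation(self, diamond_ontology):
        ann = self._propagated(diamond_ontology, [("T1", "BPO", A)])
        store = gt.EmbeddingStore({"T1": [1.0, 2.0]})
        preds = gt.transfer_annotations("Q", np.array([1.0, 2.0]), store, ann, k=1)
        assert {(p.term, p.ri) for p in preds} == {(A, 1.0), (B, 1.0), (C, 1.0)}

    def test_shared_term_outscores_private_terms(self, diamond_ontology):
        # two equidistant hits share B; A and C are private to one hit each
        ann = self._propagated(diamond_ontology, [("T1", "BPO", A)])
        ann2 = gt.AnnotationSet(propagated=True)
        for p, ns, t in [("T1", "BPO", A), ("T1", "BPO", B), ("T1", "BPO", C),
                         ("T2", "BPO", B)]:
            ann2.add(p, ns, t)
        store = gt.EmbeddingStore({"T1": [1.0, 0.0], "T2": [-1.0, 0.0]})
        preds = gt.transfer_annotations("Q", np.zeros(2), store, ann2, k=2)
        ri = {p.term: p.ri for p in preds}
        assert ri[B] > ri[A] and ri[B] > ri[C]

    def test_prediction_list_matches_per_term_recomputation(self, fixture_world):
        ont, db, queries, truth, _ = fixture_world
        qid = queries.ids[0]
        k = 3
        hits = gt.nearest_neighbors(queries[qid], db.store, k=k)
        preds = gt.transfer_annotations(qid, queries[qid], db.store,
                                        db.annotations, k=k)
        # independent recomputation, term by term
        for p in preds:
            flags = [p.term in db.annotations.terms(h.id, p.namespace) for h in hits]
            expected = sum(0.5 / (0.5 + h.distance)
                           for h, f in zip(hits, flags) if f) / k
            assert p.ri == pytest.approx(min(expected, 1.0))
        # and the term universe matches the union of hit annotations
        for ns in ("BPO", "MFO", "CCO"):
            union = set().union(*(db.annotations.terms(h.id, ns) for h in hits))
            assert {p.term for p in preds if p.namespace == ns} == union

    def test_parent_ri_dominates_child_ri(self, fixture_world):
        ont, db, queries, *_ = fixture_world
        qid = queries.ids[3]
        preds = gt.transfer_annotations(qid, queries[qid], db.store,
                                        db.annotations, k=3)
        ri = {(p.namespace, p.term): p.ri for p in preds}
        for p in preds:
            for parent in ont.parents(p.term):
                if (p.namespace, parent) in ri:
                    assert ri[(p.namespace, parent)] >= p.ri - 1e-12

    def test_determinism_byte_identical_output(self, fixture_world):
        _, db, queries, *_ = fixture_world
        outputs = []
        for _ in range(2):
            preds = gt.transfer_all(queries, db.store, db.annotations, k=2)
            buf = io.StringIO()
            gt.write_predictions(preds, buf, decimals=None)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_unpropagated_database_rejected(self, diamond_ontology):
        ann = gt.AnnotationSet()
        ann.add("T1", "BPO", A)
        store = gt.EmbeddingStore({"T1": [0.0]})
        with pytest.raises(ValidationError, match="propagated"):
            gt.transfer_annotations("Q", np.zeros(1), store, ann)


class TestThresholdAndNaive:
    def test_threshold_zero_is_identity_and_one_keeps_certain(self):
        preds = [gt.Prediction("Q", "BPO", A, 1.0),
                 gt.Prediction("Q", "BPO", B, 0.4)]
        assert gt.apply_threshold(preds, {"BPO": 0.0}) == preds
        assert gt.apply_threshold(preds, {"BPO": 1.0}) == [preds[0]]

    def test_default_thresholds_filter_count(self):
        ris = [0.36, 0.34, 0.29, 0.27, 0.30, 0.28]
        preds = [gt.Prediction("Q", ns, f"GO:91000{i:02d}", ri)
                 for i, (ns, ri) in enumerate(zip(
                     ["BPO", "BPO", "MFO", "MFO", "CCO", "CCO"], ris))]
        kept = gt.apply_threshold(preds, gt.DEFAULT_RI_THRESHOLDS)
        manual = [p for p in preds
                  if p.ri >= {"BPO": 0.35, "MFO": 0.28, "CCO": 0.29}[p.namespace]]
        assert kept == manual
        assert len(kept) == 3

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValidationError):
            gt.apply_threshold([], {"BPO": 1.5})

    def test_naive_scores_equal_term_frequencies(self, fixture_world):
        _, db, *_ = fixture_world
        freqs = gt.term_frequencies(db.annotations)
        preds = gt.naive_predict(freqs, ["Q1"])
        assert preds  # non-empty
        for p in preds:
            assert p.ri == freqs.get(p.namespace)[p.term]
        predicted = {(p.namespace, p.term) for p in preds}
        expected = {(ns, t) for ns, table in freqs.per_namespace.items()
                    for t in table}
        assert predicted == expected

    def test_prediction_file_round_trip(self, diamond_ontology, tmp_path):
        preds = [gt.Prediction("Q1", "BPO", A, 0.625), gt.Prediction("Q1", "BPO", B, 1.0)]
        buf = io.StringIO()
        gt.write_predictions(preds, buf, decimals=None)
        buf.seek(0)
        again = gt.read_predictions(buf, diamond_ontology)
        assert sorted(again) == sorted(preds)
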