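from datetime import date, timedelta

import numpy as np
import pytest

from notecast.timeline import (
    PAD_CLASS,
    WeakScoreTable,
    assemble_supervision,
    assign_labels,
    build_batch,
    impute_recurrence_date,
    split_cohort,
    threshold_weak_labels,
    truncate_pad,
)


class TestAssignLabels:
    def test_no_recurrence_all_zero(self, timeline_factory, d):
        t = timeline_factory(note_dates=[d(2010, 1, 1), d(2011, 1, 1)])
        assert assign_labels(t).tolist() == [0, 0]

    def test_within_horizon_positive(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 1, 1)], recurrence_date=d(2010, 6, 1)
        )  # 151 days ahead
        assert assign_labels(t).tolist() == [1]

    def test_beyond_horizon_negative(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 1, 1)], recurrence_date=d(2011, 6, 1)
        )  # 516 days ahead
        assert assign_labels(t).tolist() == [0]

    def test_note_after_recurrence_positive(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2012, 3, 1)], recurrence_date=d(2011, 6, 1)
        )
        assert assign_labels(t).tolist() == [1]

    def test_inclusive_boundary(self, timeline_factory, d):
        base = d(2010, 1, 1)
        t = timeline_factory(
            note_dates=[base], recurrence_date=base + timedelta(days=365)
        )
        assert assign_labels(t, horizon_days=365).tolist() == [1]
        t2 = timeline_factory(
            note_dates=[base], recurrence_date=base + timedelta(days=366)
        )
        assert assign_labels(t2, horizon_days=365).tolist() == [0]

    def test_unsorted_rejected(self, timeline_factory, d):
        t = timeline_factory(note_dates=[d(2011, 1, 1), d(2010, 1, 1)])
        with pytest.raises(ValueError):
            assign_labels(t)

    def test_horizon_monotone_on_random_timelines(self, timeline_factory, d):
        rng = np.random.default_rng(0)
        base = d(2008, 1, 1)
        for _ in range(200):
            n = int(rng.integers(1, 10))
            dates = sorted(
                base + timedelta(days=int(x)) for x in rng.integers(0, 2000, n)
            )
            rec = (
                base + timedelta(days=int(rng.integers(0, 2500)))
                if rng.random() < 0.7
                else None
            )
            t = timeline_factory(note_dates=dates, recurrence_date=rec)
            short = assign_labels(t, horizon_days=200)
            long = assign_labels(t, horizon_days=500)
            assert np.all(long >= short)


class TestTruncatePad:
    def test_padding_convention(self):
        X, y, w = truncate_pad(np.ones((3, 2)), np.array([0, 1, 0]), max_len=5)
        assert np.array_equal(X[3:], np.zeros((2, 2)))
        assert y[3:].tolist() == [PAD_CLASS, PAD_CLASS]
        assert w[3:].tolist() == [0.0, 0.0]
        assert w[:3].tolist() == [1.0, 1.0, 1.0]

    def test_truncation_keeps_first_notes(self):
        vecs = np.arange(12, dtype=float).reshape(12, 1)
        X, y, w = truncate_pad(vecs, np.zeros(12, int), max_len=10)
        assert np.array_equal(X[:, 0], np.arange(10, dtype=float))

    def test_exact_length_unchanged(self):
        vecs = np.random.default_rng(0).normal(size=(4, 3))
        X, y, w = truncate_pad(vecs, np.zeros(4, int), max_len=4)
        assert np.array_equal(X, vecs) and (w == 1.0).all()

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        for n in (1, 5, 9):
            vecs = rng.normal(size=(n, 3))
            labels = rng.integers(0, 2, n)
            X, y, w = truncate_pad(vecs, labels, max_len=8)
            keep = min(n, 8)
            real = y != PAD_CLASS
            assert real.sum() == keep
            assert np.array_equal(X[real], vecs[:keep])
            assert np.array_equal(y[real], labels[:keep])

    def test_weight_conservation(self):
        rng = np.random.default_rng(2)
        vecs = rng.normal(size=(6, 2))
        labels = rng.integers(0, 2, 6)
        _, y, w = truncate_pad(vecs, labels, max_len=10)
        assert w.sum() == (y != PAD_CLASS).sum()

    def test_class_weights_applied(self):
        _, _, w = truncate_pad(
            np.ones((2, 1)), np.array([0, 1]), max_len=3, class_weights=(0.5, 2.0)
        )
        assert w.tolist() == [0.5, 2.0, 0.0]

    def test_invalid_max_len(self):
        with pytest.raises(ValueError):
            truncate_pad(np.ones((1, 1)), np.zeros(1, int), max_len=0)


class TestWeakLabels:
    def test_threshold_zero_all_positive(self):
        t = WeakScoreTable({"a": 0.0, "b": 0.9})
        assert set(threshold_weak_labels(t, 0.0).values()) == {1}

    def test_threshold_one_all_negative_without_exact_ones(self):
        t = WeakScoreTable({"a": 0.3, "b": 0.99})
        assert set(threshold_weak_labels(t, 1.0).values()) == {0}

    def test_simple_split(self):
        t = WeakScoreTable({"a": 0.3, "b": 0.7})
        assert threshold_weak_labels(t, 0.5) == {"a": 0, "b": 1}

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            WeakScoreTable({"a": 1.2})

    def test_lower_threshold_never_fewer_positives(self):
        rng = np.random.default_rng(0)
        t = WeakScoreTable({f"n{i}": float(rng.random()) for i in range(100)})
        counts = [
            sum(threshold_weak_labels(t, thr).values())
            for thr in (0.9, 0.6, 0.3, 0.0)
        ]
        assert counts == sorted(counts)

    def test_imputed_date_is_censoring_interval_midpoint(self, timeline_factory, d):
        t = timeline_factory(note_dates=[d(2010, 1, 1), d(2010, 6, 1), d(2011, 1, 1)])
        labels = {t.notes[1].note_id: 1, t.notes[2].note_id: 1}
        # event lies between 2010-01-01 (last negative) and 2010-06-01
        # (first positive): midpoint imputation
        assert impute_recurrence_date(t, labels) == d(2010, 3, 17)
        assert impute_recurrence_date(t, {}) is None

    def test_imputed_date_first_note_positive_uses_its_date(
        self, timeline_factory, d
    ):
        t = timeline_factory(note_dates=[d(2010, 1, 1), d(2010, 6, 1)])
        labels = {t.notes[0].note_id: 1}
        assert impute_recurrence_date(t, labels) == d(2010, 1, 1)


class TestAssembleSupervision:
    def _cohorts(self, timeline_factory, d, n_manual=10, n_weak=90):
        manual = [
            timeline_factory(patient_id=f"M{i}", note_dates=[d(2010, 1, 1)], seed=i)
            for i in range(n_manual)
        ]
        weak = [
            timeline_factory(
                patient_id=f"W{i}",
                note_dates=[d(2010, 1, 1), d(2010, 6, 1)],
                seed=100 + i,
                label_source="weak",
            )
            for i in range(n_weak)
        ]
        rng = np.random.default_rng(0)
        scores = WeakScoreTable(
            {nv.note_id: float(rng.random()) for t in weak for nv in t.notes}
        )
        return manual, weak, scores

    def test_traditional_counts(self, timeline_factory, d):
        manual, weak, scores = self._cohorts(timeline_factory, d)
        sset = assemble_supervision(manual, weak, "traditional")
        assert len(sset.timelines) == 10

    def test_weak2_counts(self, timeline_factory, d):
        manual, weak, scores = self._cohorts(timeline_factory, d)
        sset = assemble_supervision(manual, weak, "weak2", weak_scores=scores)
        assert len(sset.timelines) == 100

    def test_weak2_at_least_as_many_positive_notes_as_weak1(
        self, timeline_factory, d
    ):
        manual, weak, scores = self._cohorts(timeline_factory, d)
        s1 = assemble_supervision(manual, weak, "weak1", weak_scores=scores)
        s2 = assemble_supervision(manual, weak, "weak2", weak_scores=scores)
        pos1 = sum(int(lab.sum()) for lab in s1.labels)
        pos2 = sum(int(lab.sum()) for lab in s2.labels)
        assert pos2 >= pos1

    def test_train_test_overlap_rejected(self, timeline_factory, d):
        manual, weak, scores = self._cohorts(timeline_factory, d)
        with pytest.raises(ValueError):
            assemble_supervision(manual, weak, "traditional", test_ids=["M3"])

    def test_unknown_strategy_rejected(self, timeline_factory, d):
        manual, weak, scores = self._cohorts(timeline_factory, d)
        with pytest.raises(ValueError):
            assemble_supervision(manual, weak, "weak9", weak_scores=scores)


class TestSplitCohort:
    def test_study_sized_split(self):
        ids = [f"P{i}" for i in range(894)]
        train, test = split_cohort(ids, 0.75, seed=0)
        assert len(train) == 670 and len(test) == 224

    def test_small_split(self):
        train, test = split_cohort(list("abcd"), 0.75, seed=1)
        assert len(train) == 3 and len(test) == 1

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(50)]
        assert split_cohort(ids, seed=9) == split_cohort(ids, seed=9)

    def test_disjoint_and_complete(self):
        ids = [f"P{i}" for i in range(37)]
        train, test = split_cohort(ids, 0.75, seed=2)
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["only"], 0.75, 0)


class TestBuildBatch:
    def test_shapes_and_weights(self, timeline_factory, d):
        from notecast.timeline import SupervisionSet

        tls = [
            timeline_factory(patient_id=f"P{i}", note_dates=[d(2010, 1, 1), d(2010, 2, 1)], seed=i)
            for i in range(3)
        ]
        labels = [assign_labels(t) for t in tls]
        batch = build_batch(
            SupervisionSet("traditional", tls, labels), max_len=5, dim=4
        )
        assert batch.X.shape == (3, 5, 4)
        assert batch.y.shape == (3, 5) and batch.w.shape == (3, 5)
        assert (batch.y[:, 2:] == PAD_CLASS).all()
        assert (batch.w[:, 2:] == 0).all()
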