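from datetime import date

import numpy as np
import pytest

from notecast.evaluate import (
    bootstrap_metrics,
    embedding_diagnostics,
    evaluate_notes,
    filter_test_notes,
    optimal_operating_point,
    prediction_intervals,
    roc_auc,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.normal(size=n)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)  # distinct w.p. 1
        labels = np.array([0, 1] * 15)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(3)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(4 * scores), labels) == pytest.approx(a)
        assert roc_auc(np.log(scores + 1e-9), labels) == pytest.approx(a)


def brute_force_operating_point(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = None
    for thr in cands:
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        key = (sens + spec, spec, thr)
        if best is None or key > best:
            best = key
    return best


class TestOperatingPoint:
    def test_perfect_separation(self):
        thr, sens, spec = optimal_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < thr <= 0.8

    def test_worked_example_tie_resolved_toward_specificity(self):
        # two operating points tie at J = 1.5: (sens 1.0, spec 0.5) for any
        # threshold in (0.1, 0.35] and (sens 0.5, spec 1.0) in (0.4, 0.8];
        # the specificity tie-break selects the latter
        thr, sens, spec = optimal_operating_point(
            [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        )
        assert sens + spec == pytest.approx(1.5)
        assert sens == 0.5 and spec == 1.0
        assert 0.4 < thr <= 0.8

    def test_two_point_degenerate(self):
        thr, sens, spec = optimal_operating_point([0.2, 0.9], [0, 1])
        assert sens + spec - 1 == 1.0

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)
            thr, sens, spec = optimal_operating_point(scores, labels)
            j, spec_b, thr_b = brute_force_operating_point(scores, labels)
            assert sens + spec == pytest.approx(j, abs=1e-12)
            assert spec == pytest.approx(spec_b, abs=1e-12)
            assert thr == pytest.approx(thr_b, abs=1e-12)

    def test_youden_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            labels = rng.integers(0, 2, 20)
            labels[:2] = [0, 1]
            scores = rng.random(20) + 0.3 * labels  # AUROC >= 0.5 typically
            _, sens, spec = optimal_operating_point(scores, labels)
            j = sens + spec - 1
            if roc_auc(scores, labels) >= 0.5:
                assert 0.0 <= j <= 1.0


class TestFilterTestNotes:
    def test_post_recurrence_dropped(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 12, 1), d(2011, 2, 1)],
            recurrence_date=d(2011, 1, 1),
        )
        (filtered,) = filter_test_notes([t])
        assert [nv.timestamp for nv in filtered.notes] == [d(2010, 12, 1)]

    def test_note_on_recurrence_date_kept(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2011, 1, 1)], recurrence_date=d(2011, 1, 1)
        )
        (filtered,) = filter_test_notes([t])
        assert len(filtered.notes) == 1

    def test_non_recurrent_untouched(self, timeline_factory, d):
        t = timeline_factory(note_dates=[d(2010, 1, 1)] * 5)
        (filtered,) = filter_test_notes([t])
        assert len(filtered.notes) == 5


class TestBootstrap:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        pids = [f"P{i // 4}" for i in range(40)]
        a = bootstrap_metrics(scores, labels, pids, n_boot=20, seed=5)
        b = bootstrap_metrics(scores, labels, pids, n_boot=20, seed=5)
        assert a == b

    def test_degenerate_scores_zero_auc_spread(self):
        labels = np.array([0, 1] * 20)
        scores = np.where(labels == 1, 0.9, 0.1)
        pids = [f"P{i}" for i in range(40)]
        sds = bootstrap_metrics(scores, labels, pids, n_boot=30, seed=0)
        assert sds["auroc"] == 0.0

    def test_spread_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(1)

        def spread(n_pat):
            pids = np.repeat([f"P{i}" for i in range(n_pat)], 3)
            labels = rng.integers(0, 2, len(pids))
            labels[:2] = [0, 1]
            scores = rng.random(len(pids)) + 0.4 * labels
            return bootstrap_metrics(scores, labels, pids, n_boot=60, seed=2)["auroc"]

        assert spread(200) < spread(25)

    def test_n_boot_validated(self):
        with pytest.raises(ValueError):
            bootstrap_metrics([0.1, 0.9], [0, 1], ["a", "b"], n_boot=1)

    def test_report_assembly(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60) + labels
        pids = [f"P{i // 3}" for i in range(60)]
        rep = evaluate_notes(scores, labels, pids, n_boot=20, seed=0)
        assert 0 <= rep.auroc <= 1
        assert rep.n_notes == 60 and rep.n_patients == 20
        assert np.isfinite(rep.auroc_sd)


class TestPredictionIntervals:
    def test_lead_time_from_first_crossing(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 1, 1), d(2010, 2, 5), d(2010, 8, 1)],
            recurrence_date=d(2011, 1, 1),
        )
        probs = {t.patient_id: np.array([0.1, 0.8, 0.9])}
        ivs, hist = prediction_intervals([t], probs, threshold=0.5)
        assert ivs[0].days_in_advance == (d(2011, 1, 1) - d(2010, 2, 5)).days == 330
        assert hist == {(300, 400): 1}

    def test_never_crossing_is_none(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 1, 1)], recurrence_date=d(2011, 1, 1)
        )
        ivs, hist = prediction_intervals([t], {t.patient_id: np.array([0.2])}, 0.5)
        assert ivs[0].days_in_advance is None and hist == {}

    def test_crossing_on_recurrence_date_is_zero(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2011, 1, 1)], recurrence_date=d(2011, 1, 1)
        )
        ivs, _ = prediction_intervals([t], {t.patient_id: np.array([0.9])}, 0.5)
        assert ivs[0].days_in_advance == 0

    def test_only_recurrent_patients_reported(self, timeline_factory, d):
        t = timeline_factory(note_dates=[d(2010, 1, 1)])
        ivs, _ = prediction_intervals([t], {t.patient_id: np.array([0.9])}, 0.5)
        assert ivs == []

    def test_nonnegative_after_filtering(self, timeline_factory, d):
        t = timeline_factory(
            note_dates=[d(2010, 6, 1), d(2011, 6, 1)],
            recurrence_date=d(2011, 1, 1),
        )
        (filtered,) = filter_test_notes([t])
        probs = {t.patient_id: np.full(len(filtered.notes), 1.0)}
        ivs, _ = prediction_intervals([filtered], probs, 0.5)
        assert ivs[0].days_in_advance >= 0


class TestEmbeddingDiagnostics:
    def test_two_coordinates_per_point(self):
        rng = np.random.default_rng(0)
        coords = embedding_diagnostics(rng.normal(size=(12, 6)), seed=0)
        assert coords.shape == (12, 2)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        c1 = embedding_diagnostics(X, seed=3)
        c2 = embedding_diagnostics(X, seed=3)
        assert np.allclose(c1, c2)

    def test_cluster_structure_preserved(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 4)) * 0.01
        b = rng.normal(size=(6, 4)) * 0.01 + 50.0
        coords = embedding_diagnostics(np.vstack([a, b]), seed=0)
        intra = np.linalg.norm(coords[0] - coords[1])
        inter = np.linalg.norm(coords[0] - coords[6])
        assert intra < inter

    def test_plot_written(self, tmp_path):
        rng = np.random.default_rng(3)
        out = tmp_path / "proj.png"
        embedding_diagnostics(
            rng.normal(size=(9, 3)), labels=[0, 1, 0] * 3, seed=0, plot_path=out
        )
        assert out.exists() and out.stat().st_size > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            embedding_diagnostics(np.zeros((1, 3)))
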