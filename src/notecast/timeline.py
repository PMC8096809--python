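"""Per-patient note timelines, 1-year-ahead labels, and supervision sets.

Each patient is a chronological sequence of note vectors X = (V1..Vn). The
target at note t is the patient's recurrence status one year after the
note's date: label 1 when a recurrence date exists and falls within
``horizon_days`` of the note (inclusive, and any note on or after the
recurrence date is also 1 — the status one year out is recurrent), else 0.
Sequences are truncated to the first ``max_len`` notes and right-padded
with zero vectors; padded positions carry the dedicated class 2 and sample
weight 0 so they never contribute to the loss.

Three supervision strategies assemble training cohorts:

* ``traditional`` — manually chart-reviewed patients only;
* ``weak1``       — manual plus weakly labelled patients thresholded at the
                    *higher* score cutoff (few positives, high specificity);
* ``weak2``       — manual plus weakly labelled patients thresholded at the
                    *lower* cutoff (more positives, high sensitivity).

For a weakly labelled patient, the date of the first weak-positive note is
used as the imputed recurrence date, and labels then follow the same
1-year-ahead construction as for manual patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embed import NoteVector

__all__ = [
    "PatientTimeline",
    "LabelSequence",
    "WeakScoreTable",
    "SupervisionSet",
    "SequenceBatch",
    "PAD_CLASS",
    "assign_labels",
    "truncate_pad",
    "threshold_weak_labels",
    "impute_recurrence_date",
    "assemble_supervision",
    "split_cohort",
    "build_batch",
]

PAD_CLASS = 2
STRATEGIES = ("traditional", "weak1", "weak2")


@dataclass
class PatientTimeline:
    """Chronologically ordered note vectors plus the patient's outcome."""

    patient_id: str
    notes: list[NoteVector]
    recurrence_date: date | None = None
    label_source: str = "manual"  # "manual" | "weak"

    def sort(self) -> "PatientTimeline":
        """Stable sort by (timestamp, note_id) for same-day determinism."""
        self.notes.sort(key=lambda nv: (nv.timestamp, nv.note_id))
        return self


@dataclass
class LabelSequence:
    """Per-position classes over {0 no-recurrence, 1 recurrence, 2 pad}."""

    labels: np.ndarray


@dataclass
class WeakScoreTable:
    """Per-note probabilistic recurrence scores from the upstream extractor."""

    score: dict[str, float]

    def __post_init__(self):
        for nid, s in self.score.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"weak score for note {nid!r} outside [0,1]: {s}")


@dataclass
class SupervisionSet:
    """A training cohort assembled under one supervision strategy."""

    strategy: str
    timelines: list[PatientTimeline]
    labels: list[np.ndarray] = field(default_factory=list)


@dataclass
class SequenceBatch:
    """Dense arrays ready for the sequence model: (P, T, D) inputs, (P, T)
    integer labels, (P, T) sample weights, plus the patient-id index."""

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    patient_ids: list[str]


def assign_labels(timeline: PatientTimeline, horizon_days: int = 365) -> np.ndarray:
    """1-year-ahead status per note: 1 iff recurrence occurs on or before
    ``note date + horizon_days`` (notes at or past the recurrence date are
    therefore 1); 0 otherwise. No pad positions yet."""
    dates = [nv.timestamp for nv in timeline.notes]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError(f"notes of patient {timeline.patient_id!r} are not sorted")
    rec = timeline.recurrence_date
    if rec is None:
        return np.zeros(len(dates), dtype=np.int64)
    horizon = timedelta(days=horizon_days)
    return np.array([1 if rec <= d + horizon else 0 for d in dates], dtype=np.int64)


def truncate_pad(
    vectors: np.ndarray,
    labels: np.ndarray,
    max_len: int = 800,
    class_weights: Sequence[float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fix a (n, dim) sequence to length ``max_len``.

    Longer sequences keep their first ``max_len`` notes; shorter ones are
    right-padded with zero vectors, label ``PAD_CLASS`` and weight 0. Real
    positions get ``class_weights[label]``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if vectors.shape[0] != labels.shape[0]:
        raise ValueError("vectors and labels misaligned")
    n, dim = vectors.shape
    X = np.zeros((max_len, dim))
    y = np.full(max_len, PAD_CLASS, dtype=np.int64)
    w = np.zeros(max_len)
    keep = min(n, max_len)
    X[:keep] = vectors[:keep]
    y[:keep] = labels[:keep]
    cw = np.asarray(class_weights, dtype=np.float64)
    w[:keep] = cw[y[:keep]]
    return X, y, w


def threshold_weak_labels(scores: WeakScoreTable, threshold: float) -> dict[str, int]:
    """Binarise weak scores: label 1 iff score >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    return {nid: int(s >= threshold) for nid, s in scores.score.items()}


def impute_recurrence_date(
    timeline: PatientTimeline, note_labels: Mapping[str, int]
) -> date | None:
    """Impute a recurrence date from per-note weak detection labels.

    The extractor detects *current* status, so the event date is
    interval-censored between the last weak-negative note and the first
    weak-positive one; the midpoint of that interval is the standard
    unbiased choice (using the positive note's own date would bias every
    weak label late by about half an inter-visit gap). When the first
    note is already positive its date is used. None when no note is
    positive.
    """
    prev: date | None = None
    for nv in timeline.notes:
        if note_labels.get(nv.note_id, 0) == 1:
            if prev is None:
                return nv.timestamp
            return prev + (nv.timestamp - prev) / 2
        prev = nv.timestamp
    return None


def assemble_supervision(
    manual: Sequence[PatientTimeline],
    weak: Sequence[PatientTimeline],
    strategy: str,
    weak_scores: WeakScoreTable | None = None,
    threshold_hi: float = 0.85,
    threshold_lo: float = 0.5,
    test_ids: Iterable[str] = (),
    horizon_days: int = 365,
) -> SupervisionSet:
    """Build the training cohort for one strategy, with labels attached.

    ``traditional`` uses manual patients only; ``weak1``/``weak2`` add the
    weak cohort with recurrence dates imputed from scores thresholded at
    the high/low cutoff respectively. Raises when any training patient also
    appears in ``test_ids``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    test = set(test_ids)
    overlap = {t.patient_id for t in manual} & test
    if overlap:
        raise ValueError(f"train/test patient overlap: {sorted(overlap)[:5]}")
    manual_ids = {t.patient_id for t in manual}
    if manual_ids & {t.patient_id for t in weak}:
        raise ValueError("manual and weak cohorts must be disjoint")

    timelines = [t for t in manual]
    if strategy != "traditional":
        if weak_scores is None:
            raise ValueError("weak strategies need a WeakScoreTable")
        thr = threshold_hi if strategy == "weak1" else threshold_lo
        note_labels = threshold_weak_labels(weak_scores, thr)
        for t in weak:
            if t.patient_id in test:
                raise ValueError(f"weak patient {t.patient_id!r} is in the test set")
            rec = impute_recurrence_date(t, note_labels)
            timelines.append(replace(t, recurrence_date=rec, label_source="weak"))

    labels = [assign_labels(t, horizon_days) for t in timelines]
    return SupervisionSet(strategy, timelines, labels)


def split_cohort(
    patient_ids: Sequence[str], train_frac: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Patient-level random split, deterministic for a fixed seed."""
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(len(ids) * train_frac)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def build_batch(
    sset: SupervisionSet,
    max_len: int = 800,
    dim: int | None = None,
    class_weights: Sequence[float] = (1.0, 1.0),
) -> SequenceBatch:
    """Stack a supervision set into dense (P, T, D) model-ready arrays."""
    if not sset.timelines:
        raise ValueError("empty supervision set")
    if dim is None:
        for t in sset.timelines:
            if t.notes:
                dim = len(t.notes[0].v)
                break
        if dim is None:
            raise ValueError("cannot infer vector dimension from empty timelines")
    Xs, ys, ws, pids = [], [], [], []
    for t, lab in zip(sset.timelines, sset.labels):
        vecs = (
            np.stack([nv.v for nv in t.notes]) if t.notes else np.zeros((0, dim))
        )
        X, y, w = truncate_pad(vecs, lab, max_len=max_len, class_weights=class_weights)
        Xs.append(X)
        ys.append(y)
        ws.append(w)
        pids.append(t.patient_id)
    return SequenceBatch(np.stack(Xs), np.stack(ys), np.stack(ws), pids)
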