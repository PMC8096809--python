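"""Note-level evaluation: ROC analysis, operating point, uncertainty.

Every real (non-padded) test note is one evaluation sample. Test notes
dated strictly after the patient's recurrence date are excluded first, so
the metrics measure prediction ahead of the event rather than detection.
AUROC is computed as the Mann-Whitney concordance probability (ties count
1/2); the operating point maximises Youden's J = sensitivity +
specificity - 1 over the exhaustive threshold grid. Uncertainty comes from
a patient-level bootstrap, which respects the correlation between notes of
the same patient. Prediction intervals report, per recurrence-positive
patient, how many days before the confirmed recurrence the predicted
probability first crossed the operating threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .timeline import PatientTimeline

__all__ = [
    "EvalReport",
    "PredictionInterval",
    "filter_test_notes",
    "roc_auc",
    "optimal_operating_point",
    "bootstrap_metrics",
    "evaluate_notes",
    "prediction_intervals",
    "embedding_diagnostics",
]


@dataclass
class EvalReport:
    """AUROC and operating-point metrics with bootstrap spreads."""

    auroc: float
    threshold: float
    sensitivity: float
    specificity: float
    auroc_sd: float = float("nan")
    sensitivity_sd: float = float("nan")
    specificity_sd: float = float("nan")
    n_notes: int = 0
    n_patients: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


@dataclass(frozen=True)
class PredictionInterval:
    """Lead time between first above-threshold prediction and recurrence."""

    patient_id: str
    days_in_advance: int | None


def filter_test_notes(timelines: Sequence[PatientTimeline]) -> list[PatientTimeline]:
    """Drop test notes dated strictly after the recurrence date.

    Notes on the recurrence date itself are kept; non-recurrent patients
    are untouched.
    """
    out = []
    for t in timelines:
        if t.recurrence_date is None:
            out.append(t)
        else:
            kept = [nv for nv in t.notes if nv.timestamp <= t.recurrence_date]
            out.append(_dc_replace(t, notes=kept))
    return out


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_binary(labels)
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def optimal_operating_point(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity (Youden's J).

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus one below the minimum and one above the maximum; among
    J-ties, the threshold with higher specificity (then the higher
    threshold) wins. Returns (threshold, sensitivity, specificity); a score
    counts as positive when it is >= the threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_binary(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    sens = (n_pos - np.searchsorted(pos_sorted, candidates, side="left")) / n_pos
    spec = np.searchsorted(neg_sorted, candidates, side="left") / n_neg
    # lexicographic maximum of (J, specificity, threshold)
    best = np.lexsort((candidates, spec, sens + spec))[-1]
    return float(candidates[best]), float(sens[best]), float(spec[best])


def evaluate_notes(
    scores: Sequence[float],
    labels: Sequence[int],
    patient_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full note-level report: AUROC, operating point, bootstrap spreads."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    auc = roc_auc(scores, labels)
    thr, sens, spec = optimal_operating_point(scores, labels)
    sds = bootstrap_metrics(scores, labels, patient_ids, n_boot=n_boot, seed=seed)
    return EvalReport(
        auroc=auc,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        auroc_sd=sds["auroc"],
        sensitivity_sd=sds["sensitivity"],
        specificity_sd=sds["specificity"],
        n_notes=len(scores),
        n_patients=len(set(patient_ids)),
    )


def bootstrap_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    patient_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Patient-level bootstrap standard deviations of the report metrics.

    Patients are resampled with replacement; resamples that lose one of
    the classes are skipped (they carry no ROC information).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pids = np.asarray(patient_ids)
    uniq = np.unique(pids)
    by_patient = {p: np.flatnonzero(pids == p) for p in uniq}
    rng = np.random.default_rng(seed)
    aucs, senss, specs = [], [], []
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([by_patient[p] for p in chosen])
        if len(np.unique(labels[idx])) < 2:
            continue
        aucs.append(roc_auc(scores[idx], labels[idx]))
        _, se, sp = optimal_operating_point(scores[idx], labels[idx])
        senss.append(se)
        specs.append(sp)
    def sd(x):
        return float(np.std(x)) if len(x) >= 2 else float("nan")
    return {"auroc": sd(aucs), "sensitivity": sd(senss), "specificity": sd(specs)}


def prediction_intervals(
    timelines: Sequence[PatientTimeline],
    probabilities: dict[str, np.ndarray],
    threshold: float,
    bin_days: int = 100,
) -> tuple[list[PredictionInterval], dict[tuple[int, int], int]]:
    """Lead times for recurrence-positive patients, plus histogram counts.

    For each patient the earliest note whose predicted probability reaches
    the threshold sets the alarm date; ``days_in_advance`` is the gap to
    the confirmed recurrence date (None when the threshold is never
    crossed). Counts are binned in ``bin_days``-day bins starting at 0.
    """
    intervals: list[PredictionInterval] = []
    for t in timelines:
        if t.recurrence_date is None:
            continue
        probs = probabilities.get(t.patient_id)
        days = None
        if probs is not None:
            for nv, pr in zip(t.notes, probs):
                if pr >= threshold:
                    days = (t.recurrence_date - nv.timestamp).days
                    break
        intervals.append(PredictionInterval(t.patient_id, days))
    hist: dict[tuple[int, int], int] = {}
    for iv in intervals:
        if iv.days_in_advance is None:
            continue
        lo = (iv.days_in_advance // bin_days) * bin_days
        key = (lo, lo + bin_days)
        hist[key] = hist.get(key, 0) + 1
    return intervals, hist


def embedding_diagnostics(
    vectors: np.ndarray,
    labels: Sequence | None = None,
    seed: int = 0,
    perplexity: float | None = None,
    plot_path=None,
):
    """2-D t-SNE projection of word or note vectors for visual inspection.

    Returns the (n, 2) coordinates; when ``plot_path`` is given a scatter
    coloured by ``labels`` is written there.
    """
    from sklearn.manifold import TSNE

    vectors = np.asarray(vectors, dtype=np.float64)
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to project")
    if perplexity is None:
        perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    coords = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca" if n > 3 else "random",
    ).fit_transform(vectors)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        if labels is not None:
            labels = np.asarray(labels)
            for val in np.unique(labels):
                pts = coords[labels == val]
                ax.scatter(pts[:, 0], pts[:, 1], s=8, label=str(val), alpha=0.7)
            ax.legend(title="class", fontsize=8)
        else:
            ax.scatter(coords[:, 0], coords[:, 1], s=8, alpha=0.7)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return coords
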