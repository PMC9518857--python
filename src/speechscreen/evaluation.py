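"""Prediction scoring, confusion-matrix metrics, ROC curve and AUROC.

The positive class is index 1. The ROC curve is built by sweeping the
decision threshold across the unique scores from high to low; tied scores
move the operating point in one simultaneous horizontal+vertical step,
which makes the trapezoidal area identical to the rank-sum
(probability-of-correct-ranking) estimator with half credit for ties.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mfcc import FeatureDataset

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "EvaluationReport",
    "predict",
    "confusion_at_threshold",
    "roc_and_auroc",
    "aggregate_by_participant",
    "evaluate_scores",
    "evaluate_model",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass
class RocCurve:
    points: np.ndarray  # (n, 2) ordered (fpr, tpr), from (0,0) to (1,1)
    thresholds: np.ndarray
    auroc: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("ROC needs at least the two endpoint operating points")
        if not (np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValueError("ROC points must be monotone non-decreasing")
        self.points = pts


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    roc: RocCurve
    granularity: str = "segment"  # or "participant"

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity

    @property
    def auroc(self) -> float:
        return self.roc.auroc


def predict(model, segments: np.ndarray) -> np.ndarray:
    """Positive-class softmax probability per segment, in [0, 1]."""
    probs = model.predict_proba(np.asarray(segments, dtype=np.float64))
    return probs[:, 1]


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Exact confusion counts with ``score >= threshold`` called positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be non-empty and equal-length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def roc_and_auroc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC by threshold sweep over the unique scores, AUROC by trapezoid."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(np.float64)
    # collapse ties: one step per distinct score value
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tp_cum = np.cumsum(sorted_pos)[distinct]
    fp_cum = np.cumsum(1.0 - sorted_pos)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), thresholds=thresholds, auroc=auroc)


def aggregate_by_participant(
    scores: np.ndarray,
    labels: np.ndarray,
    participant_ids: list[str],
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Collapse segment scores to one row per participant.

    Returns (mean_scores, majority_vote_predictions, labels, ids). The
    participant score used for the ROC is the mean segment score; the hard
    prediction is the majority vote over thresholded segment predictions,
    ties called positive.
    """
    ids = sorted(set(participant_ids))
    pid_arr = np.asarray(participant_ids)
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    mean_scores, votes, part_labels = [], [], []
    for pid in ids:
        mask = pid_arr == pid
        seg_labels = np.unique(labels[mask])
        if seg_labels.size != 1:
            raise ValueError(f"participant {pid!r} has inconsistent segment labels")
        part_labels.append(int(seg_labels[0]))
        mean_scores.append(float(scores[mask].mean()))
        frac_pos = float(np.mean(scores[mask] >= threshold))
        votes.append(1 if frac_pos >= 0.5 else 0)
    return (
        np.array(mean_scores),
        np.array(votes, dtype=np.int64),
        np.array(part_labels, dtype=np.int64),
        ids,
    )


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    participant_ids: list[str] | None = None,
    granularity: str = "segment",
    threshold: float = 0.5,
) -> EvaluationReport:
    """Build a full report from scores at the requested granularity."""
    if granularity == "participant":
        if participant_ids is None:
            raise ValueError("participant granularity needs participant_ids")
        mean_scores, votes, plabels, _ = aggregate_by_participant(
            scores, labels, participant_ids, threshold
        )
        roc = roc_and_auroc(mean_scores, plabels)
        pos = plabels == 1
        pred = votes == 1
        confusion = ConfusionMatrix(
            tp=int(np.sum(pred & pos)),
            fp=int(np.sum(pred & ~pos)),
            tn=int(np.sum(~pred & ~pos)),
            fn=int(np.sum(~pred & pos)),
        )
    elif granularity == "segment":
        confusion = confusion_at_threshold(scores, labels, threshold)
        roc = roc_and_auroc(scores, labels)
    else:
        raise ValueError("granularity must be 'segment' or 'participant'")
    return EvaluationReport(confusion=confusion, roc=roc, granularity=granularity)


def evaluate_model(
    model,
    dataset: FeatureDataset,
    participant_ids: set[str] | None = None,
    granularity: str = "segment",
    threshold: float = 0.5,
) -> EvaluationReport:
    """Score a dataset (optionally restricted to a participant subset)."""
    segments = dataset.segments
    if participant_ids is not None:
        segments = [s for s in segments if s.participant_id in participant_ids]
    if not segments:
        raise ValueError("no segments to evaluate")
    X = np.stack([s.features for s in segments])
    y = np.array([s.label for s in segments], dtype=np.int64)
    pids = [s.participant_id for s in segments]
    scores = predict(model, X)
    return evaluate_scores(scores, y, pids, granularity, threshold)


def write_report(report: EvaluationReport, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write metrics and ROC CSVs; returns the written paths."""
    if report.roc.points.shape[0] < 2:
        raise ValueError("refusing to write an empty ROC")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = out_dir / "metrics.csv"
    c = report.confusion
    with open(metrics_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["granularity", "tp", "fp", "tn", "fn",
             "accuracy", "sensitivity", "specificity", "auroc"]
        )
        writer.writerow(
            [report.granularity, c.tp, c.fp, c.tn, c.fn,
             repr(report.accuracy), repr(report.sensitivity),
             repr(report.specificity), repr(report.auroc)]
        )
    roc_path = out_dir / "roc.csv"
    with open(roc_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for thr, (fpr, tpr) in zip(report.roc.thresholds, report.roc.points):
            writer.writerow([repr(float(thr)), repr(float(fpr)), repr(float(tpr))])
    return {"metrics": metrics_path, "roc": roc_path}


def read_report(out_dir: str | os.PathLike) -> EvaluationReport:
    """Re-read a report written by :func:`write_report`, numbers exact."""
    out_dir = Path(out_dir)
    with open(out_dir / "metrics.csv", newline="") as fh:
        row = list(csv.DictReader(fh))[0]
    with open(out_dir / "roc.csv", newline="") as fh:
        rows = list(csv.DictReader(fh))
    points = np.array([[float(r["fpr"]), float(r["tpr"])] for r in rows])
    thresholds = np.array([float(r["threshold"]) for r in rows])
    roc = RocCurve(points=points, thresholds=thresholds, auroc=float(row["auroc"]))
    confusion = ConfusionMatrix(
        tp=int(row["tp"]), fp=int(row["fp"]), tn=int(row["tn"]), fn=int(row["fn"])
    )
    return EvaluationReport(confusion=confusion, roc=roc, granularity=row["granularity"])
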