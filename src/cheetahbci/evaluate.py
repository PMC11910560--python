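"""Session scoring: confusion matrices, accuracy and per-task/per-subject tables.

Accuracy follows the binary definition (TP + TN) / (TP + FP + TN + FN),
extended to the four-class task in one-vs-rest form and macro-averaged;
because that definition counts true negatives it is *not* the same number
as the pooled trial accuracy (correct / total), so both are reported.
Precision, recall and F1 are likewise one-vs-rest macro averages; a class
with a zero denominator contributes 0 to the average (with a warning).

Score sheets — per-subject, per-task correct-trial counts from a session —
aggregate into exactly the quantities a BCI study tabulates: task-wise
accuracy, subject-wise accuracy, the mean/sd of subject accuracies, the
pooled correct-trial percentage, and the wrongly-classified total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .synthetic import TASKS


def one_vs_rest_counts(cm: np.ndarray) -> pd.DataFrame:
    """TP/TN/FP/FN per class from a square confusion matrix (rows = truth)."""
    cm = np.asarray(cm)
    total = cm.sum()
    tp = np.diag(cm).astype(int)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    return pd.DataFrame({"TP": tp, "TN": tn, "FP": fp, "FN": fn})


def accuracy(tp: float, tn: float, fp: float, fn: float) -> float:
    """(TP + TN) / (TP + FP + TN + FN) as a percentage."""
    denom = tp + fp + tn + fn
    if denom <= 0:
        raise ValueError("counts must not be all zero")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    return 100.0 * (tp + tn) / denom


def _safe_ratio(num: float, denom: float, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name}: zero denominator; defining the metric as 0 for this class")
        return 0.0
    return num / denom


def macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """Macro-averaged one-vs-rest accuracy, precision, recall, F1 (percent)."""
    counts = one_vs_rest_counts(cm)
    accs, precs, recs, f1s = [], [], [], []
    for row in counts.itertuples():
        accs.append(accuracy(row.TP, row.TN, row.FP, row.FN))
        p = _safe_ratio(row.TP, row.TP + row.FP, "precision")
        r = _safe_ratio(row.TP, row.TP + row.FN, "recall")
        precs.append(p)
        recs.append(r)
        f1s.append(_safe_ratio(2 * p * r, p + r, "F1"))
    return {
        "macro_accuracy": float(np.mean(accs)),
        "macro_precision": 100.0 * float(np.mean(precs)),
        "macro_recall": 100.0 * float(np.mean(recs)),
        "macro_f1": 100.0 * float(np.mean(f1s)),
    }


@dataclass
class EvalReport:
    """Full scorecard of one classified session."""

    confusion: pd.DataFrame  # 4x4, rows = true task
    class_counts: pd.DataFrame  # TP/TN/FP/FN per task
    accuracy: float  # pooled correct/total, percent
    macro_accuracy: float  # one-vs-rest accuracy, macro-averaged
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_task_accuracy: pd.Series  # percent correct per true task
    per_task_correct: pd.Series  # raw correct counts per true task
    per_subject_accuracy: pd.Series  # percent correct per subject
    subject_mean: float  # mean of per-subject accuracies
    subject_sd: float
    n_trials: int
    n_wrong: int
    mode: str = "offline"

    def summary(self) -> str:
        lines = [
            f"Session scorecard ({self.mode} mode, {self.n_trials} trials)",
            "=" * 54,
            f"Pooled trial accuracy     : {self.accuracy:6.2f} %  ({self.n_trials - self.n_wrong}/{self.n_trials} correct)",
            f"Wrongly classified trials : {self.n_wrong}",
            f"Macro OvR accuracy        : {self.macro_accuracy:6.2f} %",
            f"Macro precision/recall/F1 : {self.macro_precision:.2f} / {self.macro_recall:.2f} / {self.macro_f1:.2f} %",
            f"Subject-wise accuracy     : {self.subject_mean:6.2f} +/- {self.subject_sd:.2f} %",
            "",
            "Per-task accuracy (%):",
        ]
        for task, val in self.per_task_accuracy.items():
            lines.append(f"  {task:<8s} {val:6.2f}")
        lines += ["", "Confusion matrix (rows = true task):", self.confusion.to_string()]
        return "\n".join(lines)

    def to_tables(self) -> pd.DataFrame:
        """Per-subject table: correct counts per task, wrong total, accuracy."""
        return self._subject_table

    _subject_table: pd.DataFrame = field(default=None, repr=False)


def score_session(predictions: pd.DataFrame, mode: str = "offline") -> EvalReport:
    """Score a prediction manifest.

    ``predictions`` needs columns subject_id, label (truth) and prediction;
    every trial must carry a prediction.
    """
    required = {"subject_id", "label", "prediction"}
    missing_cols = required - set(predictions.columns)
    if missing_cols:
        raise ValueError(f"prediction manifest missing columns: {sorted(missing_cols)}")
    missing = predictions[predictions["prediction"].isna()]
    if len(missing):
        ids = [
            f"{r.subject_id}/{r.label}/{getattr(r, 'trial_index', '?')}"
            for r in missing.itertuples()
        ]
        raise ValueError(f"missing predictions for trials: {ids}")

    labels = [t for t in TASKS if t in set(predictions["label"]) | set(predictions["prediction"])]
    cm = _sk_confusion(predictions["label"], predictions["prediction"], labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    correct = predictions["label"] == predictions["prediction"]
    n = len(predictions)
    n_wrong = int((~correct).sum())

    per_task_correct = (
        correct.groupby(predictions["label"]).sum().reindex(labels).astype(int)
    )
    per_task_total = predictions.groupby("label").size().reindex(labels)
    per_task_acc = 100.0 * per_task_correct / per_task_total
    per_subject_acc = 100.0 * correct.groupby(predictions["subject_id"]).mean()
    per_subject_acc = per_subject_acc.sort_index()

    macro = macro_metrics(cm)
    subject_table = (
        predictions.assign(correct=correct)
        .pivot_table(index="subject_id", columns="label", values="correct", aggfunc="sum")
        .reindex(columns=labels)
    )
    subject_table["wrong"] = (
        predictions.groupby("subject_id").size() - correct.groupby(predictions["subject_id"]).sum()
    ).astype(int)
    subject_table["accuracy"] = per_subject_acc

    report = EvalReport(
        confusion=confusion,
        class_counts=one_vs_rest_counts(cm).set_axis(labels, axis=0),
        accuracy=100.0 * correct.mean(),
        per_task_accuracy=per_task_acc,
        per_task_correct=per_task_correct,
        per_subject_accuracy=per_subject_acc,
        subject_mean=float(per_subject_acc.mean()),
        subject_sd=float(per_subject_acc.std(ddof=1)) if len(per_subject_acc) > 1 else 0.0,
        n_trials=n,
        n_wrong=n_wrong,
        mode=mode,
        **macro,
    )
    report._subject_table = subject_table
    return report


# ---------------------------------------------------------------------------
# score-sheet aggregation (per-subject x per-task correct-count tables)
# ---------------------------------------------------------------------------

def aggregate_scoresheet(counts: pd.DataFrame, trials_per_cell: int = 10) -> dict:
    """Aggregate a per-subject x per-task correct-count table.

    ``counts`` has one row per subject and one column per task; entry =
    number of correctly classified trials out of ``trials_per_cell``.
    Returns task-wise accuracy (%), subject-wise accuracy (%), the mean of
    subject accuracies, the pooled percent correct / percent wrong, and the
    wrongly-classified total.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any() or (counts.values > trials_per_cell).any():
        raise ValueError(f"correct counts must lie in [0, {trials_per_cell}]")
    n_subjects = len(counts)
    trials_per_subject = trials_per_cell * counts.shape[1]
    total = n_subjects * trials_per_subject

    per_task_correct = counts.sum(axis=0)
    task_accuracy = 100.0 * per_task_correct / (n_subjects * trials_per_cell)
    subject_accuracy = 100.0 * counts.sum(axis=1) / trials_per_subject
    n_correct = float(counts.values.sum())
    return {
        "task_accuracy": task_accuracy,
        "subject_accuracy": subject_accuracy,
        "subject_mean_accuracy": float(subject_accuracy.mean()),
        "subject_sd_accuracy": float(subject_accuracy.std(ddof=1)),
        "pooled_percent_correct": 100.0 * n_correct / total,
        "pooled_percent_wrong": 100.0 * (total - n_correct) / total,
        "n_wrong": int(round(total - n_correct)),
        "n_trials": int(total),
    }
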