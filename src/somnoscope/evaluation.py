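"""Evaluation surfaces: confusion-matrix metrics, ROC sweep, per-subject
accuracy tables and probability-time curve export.

Precision, recall, f1 and accuracy follow the standard 2x2 definitions
with the drowsy/anomalous class as positive. Undefined ratios (0/0) are
reported as None — a distinguished null — never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SymptomStream

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics",
    "roc_points",
    "per_subject_accuracy",
    "export_probability_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """2x2 cross-tabulation of binary sequences (positive class = 1)."""
    p = np.asarray(predicted, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"length mismatch: predicted {p.shape}, truth {t.shape}")
    if p.size == 0:
        raise ValueError("empty sequences")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), f1 their harmonic mean,
    accuracy = (TP+TN)/N. Any 0/0 ratio becomes None."""
    if c.n == 0:
        raise ValueError("no samples")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=(c.tp + c.tn) / c.n,
    )


def roc_points(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC sweep over the unique scores, descending; returns (FPR, TPR, AUC).

    Thresholds visit every distinct score, so tied scores enter en bloc
    and contribute diagonal segments (half credit under the trapezoidal
    area, matching the pairwise-comparison probability with ties at 1/2).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D sequences")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC sweep")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # group boundaries where the score strictly drops
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [s.size - 1]])
    tp_cum = np.cumsum(t_sorted)[cut]
    fp_cum = np.cumsum(1 - t_sorted)[cut]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


def per_subject_accuracy(
    decisions, truth, subjects, out_csv: str | Path | None = None
) -> pd.DataFrame:
    """Accuracy within each subject; the source table for the heat plot.

    decisions/truth: binary sequences; subjects: parallel subject ids.
    The pooled sample-weighted mean of the rows equals overall accuracy.
    """
    p = np.asarray(decisions, dtype=int)
    t = np.asarray(truth, dtype=int)
    s = np.asarray(subjects)
    if not (p.shape == t.shape == s.shape):
        raise ValueError("decisions, truth and subjects must align")
    df = pd.DataFrame({"subject_id": s, "correct": (p == t).astype(int)})
    table = (
        df.groupby("subject_id", sort=True)["correct"]
        .agg(n="count", accuracy="mean")
        .reset_index()
    )
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def export_probability_curve(
    stream: SymptomStream, out_path: str | Path, plot: bool = True
) -> Path:
    """Write the probability-time curve as CSV (always) and PNG (optional).

    out_path is the CSV path; the plot lands next to it with a .png
    suffix. Plotting is headless-safe and failures there never block the
    CSV export.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    out_path = Path(out_path)
    stream.to_csv(out_path)
    if plot:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(8, 3))
            ax.plot(stream.time_s, stream.p_mouth, color="tab:red", label="mouth anomaly")
            ax.plot(stream.time_s, stream.p_eye, color="tab:orange", label="eye anomaly")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("predicted probability")
            ax.set_ylim(-0.02, 1.02)
            ax.legend(loc="upper right")
            fig.tight_layout()
            fig.savefig(out_path.with_suffix(".png"), dpi=120)
            plt.close(fig)
        except Exception:  # plotting is best-effort; CSV is the artifact of record
            pass
    return out_path
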