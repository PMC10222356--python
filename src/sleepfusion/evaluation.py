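"""Confusion matrices and sleep-staging metrics.

Per-class scores come from one-vs-rest marginals of the 5x5 confusion
matrix (rows = true stage, columns = predicted stage):

    ACC_i = (TP_i + TN_i) / N          PPV_i = TP_i / (TP_i + FP_i)
    SE_i  = TP_i / (TP_i + FN_i)       F1_i  = 2 PPV_i SE_i / (PPV_i + SE_i)

Overall accuracy is trace/N, the overall F1 score the unweighted mean of the
per-class F1 values, and chance-corrected agreement is Cohen's kappa
Kp = (Po - Pe)/(1 - Pe) with Po = trace/N and Pe the expected agreement from
the row/column marginals. A second kappa variant replaces Po with the mean
one-vs-rest accuracy (ACCavg), a non-standard reading occasionally printed in
the sleep literature; it is selectable but never the default.

Zero-denominator cases (a class absent from both truth and prediction) yield
0 with a degeneracy flag rather than an exception, so reports on skewed
synthetic runs are always complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_NAMES",
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricReport",
    "confusion",
    "per_class_counts",
    "class_metrics",
    "kappa",
    "report",
]

STAGE_NAMES = ("W", "S1", "S2", "S3", "REM")


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; entry (r, c) = epochs of true stage r predicted c."""

    counts: np.ndarray
    class_names: tuple[str, ...] = STAGE_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")
        if len(self.class_names) != self.counts.shape[0]:
            self.class_names = tuple(str(i) for i in range(self.counts.shape[0]))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        names = list(self.class_names)
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index_label="true\\pred")
        return path


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single stage."""

    acc: float
    ppv: float
    se: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricReport:
    """Tables-style report: per-class metrics plus overall ACC, macro F1, Kp."""

    per_class: list[ClassMetrics]
    overall_acc: float
    overall_f1: float
    kp: float
    acc_avg: float
    pe: float
    class_names: tuple[str, ...] = STAGE_NAMES

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, m in zip(self.class_names, self.per_class):
            rows.append(
                {
                    "class": name,
                    "ACC": m.acc,
                    "PPV": m.ppv,
                    "SE": m.se,
                    "F1": m.f1,
                    "degenerate": m.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        """Overall row followed by per-class F1 columns (journal table order)."""
        path = Path(path)
        row: dict[str, float] = {
            "Acc(%)": 100.0 * self.overall_acc,
            "Kp": self.kp,
            "F1(%)": 100.0 * self.overall_f1,
        }
        for name, m in zip(self.class_names, self.per_class):
            row[f"F1_{name}(%)"] = 100.0 * m.f1
        pd.DataFrame([row]).to_csv(path, index=False)
        return path


def confusion(true_labels, predicted) -> ConfusionMatrix:
    """Tally epochs into a 5x5 matrix of (true, predicted) stage codes."""
    true_labels = np.asarray(true_labels, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if true_labels.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {true_labels.shape} true vs {predicted.shape} predicted"
        )
    k = len(STAGE_NAMES)
    if len(true_labels) and (
        true_labels.min() < 0 or true_labels.max() >= k
        or predicted.min() < 0 or predicted.max() >= k
    ):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (true_labels, predicted), 1)
    return ConfusionMatrix(counts)


def per_class_counts(cm: ConfusionMatrix, i: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for class i from the confusion-matrix marginals."""
    if not 0 <= i < cm.n_classes:
        raise IndexError(f"class index {i} out of range 0..{cm.n_classes - 1}")
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def class_metrics(cm: ConfusionMatrix, i: int) -> ClassMetrics:
    """One-vs-rest ACC/PPV/SE/F1 for class i; zero denominators flagged."""
    tp, fp, tn, fn = per_class_counts(cm, i)
    acc, d_acc = _safe_div(tp + tn, tp + tn + fp + fn)
    ppv, d_ppv = _safe_div(tp, tp + fp)
    se, d_se = _safe_div(tp, tp + fn)
    f1, d_f1 = _safe_div(2.0 * ppv * se, ppv + se)
    return ClassMetrics(acc, ppv, se, f1, degenerate=d_acc or d_ppv or d_se or d_f1)


def kappa(cm: ConfusionMatrix, variant: str = "standard") -> float:
    """Chance-corrected agreement Kp = (Po - Pe) / (1 - Pe).

    ``standard`` (default) is Cohen's kappa: Po = trace/N and
    Pe = sum_i row_i * col_i / N^2. ``literal_avg_acc`` substitutes the mean
    one-vs-rest accuracy (ACCavg) for Po — a non-standard formulation found
    in some sleep-staging reports, provided for comparability only.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1).astype(np.float64)
    cols = cm.counts.sum(axis=0).astype(np.float64)
    pe = float(np.dot(rows, cols)) / (n * n)
    if pe >= 1.0:
        raise ValueError("Pe = 1 (all mass in one marginal pair); kappa undefined")
    if variant == "standard":
        po = float(np.trace(cm.counts)) / n
    elif variant == "literal_avg_acc":
        po = float(np.mean([class_metrics(cm, i).acc for i in range(cm.n_classes)]))
    else:
        raise ValueError(f"unknown kappa variant {variant!r}")
    return (po - pe) / (1.0 - pe)


def report(cm: ConfusionMatrix, kappa_variant: str = "standard") -> MetricReport:
    """Full metric report from one confusion matrix.

    Overall ACC = trace/N (standard multiclass accuracy), overall F1 the
    unweighted mean of per-class F1, Kp per :func:`kappa`.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    per = [class_metrics(cm, i) for i in range(cm.n_classes)]
    rows = cm.counts.sum(axis=1).astype(np.float64)
    cols = cm.counts.sum(axis=0).astype(np.float64)
    return MetricReport(
        per_class=per,
        overall_acc=float(np.trace(cm.counts)) / n,
        overall_f1=float(np.mean([m.f1 for m in per])),
        kp=kappa(cm, kappa_variant),
        acc_avg=float(np.mean([m.acc for m in per])),
        pe=float(np.dot(rows, cols)) / (n * n),
        class_names=cm.class_names,
    )
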