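"""Evaluation battery: confusion matrix, Acc/Se/Sp/Pre/F1 and ROC/AUC.

All rate metrics are one-vs-rest per class, reported as percentages:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Se  = TP / (TP + FN)            (sensitivity / recall)
    Sp  = TN / (TN + FP)            (specificity)
    Pre = TP / (TP + FP)            (precision)
    F1  = 2 * Se * Pre / (Se + Pre) (harmonic mean)

AUC is the area under the one-vs-rest ROC curve (a fraction in [0, 1],
equal to the Mann-Whitney concordant-pair statistic, ties counted 0.5).
Metrics with a zero denominator are reported as NaN and flagged, never as
0, to avoid silently inflating F1.  Percentages round half-up to one
decimal for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

from .labels import CLASS_ORDER, RhythmLabel, as_label


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows = true class, columns = predicted, in CLASS_ORDER."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(CLASS_ORDER)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError(f"counts must be a non-negative {k}x{k} matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("true\\pred\t" + "\t".join(str(c) for c in CLASS_ORDER) + "\n")
            for i, lab in enumerate(CLASS_ORDER):
                fh.write(str(lab) + "\t" + "\t".join(map(str, self.counts[i])) + "\n")


@dataclass
class ClassMetrics:
    acc: float
    se: float
    sp: float
    pre: float
    f1: float
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)


@dataclass
class MetricsReport:
    per_class: dict[RhythmLabel, ClassMetrics]
    overall_accuracy: float  # percentage, recording level

    def to_markdown(self) -> str:
        lines = ["| Class | Accuracy | Sensitivity | Specificity | Precision | F1-score | AUC |",
                 "|---|---|---|---|---|---|---|"]

        def pct(v):
            return "-" if v is None or np.isnan(v) else f"{round_pct(v)}%"

        for lab in CLASS_ORDER:
            m = self.per_class[lab]
            auc = "-" if m.auc is None else f"{m.auc:.3f}"
            lines.append(
                f"| {lab} | {pct(m.acc)} | {pct(m.se)} | {pct(m.sp)} | {pct(m.pre)} | {pct(m.f1)} | {auc} |"
            )
        lines.append(f"| Total | {round_pct(self.overall_accuracy)}% | - | - | - | - | - |")
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("class\tacc\tse\tsp\tpre\tf1\tauc\n")
            for lab in CLASS_ORDER:
                m = self.per_class[lab]
                auc = "" if m.auc is None else f"{m.auc:.6f}"
                fh.write(f"{lab}\t{m.acc:.6f}\t{m.se:.6f}\t{m.sp:.6f}\t{m.pre:.6f}\t{m.f1:.6f}\t{auc}\n")
            fh.write(f"overall\t{self.overall_accuracy:.6f}\t\t\t\t\t\n")


def round_pct(value: float, ndigits: int = 1) -> float:
    """Half-up rounding of a percentage (97.35 -> 97.4), matching report style."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count matrix over the fixed class order."""
    yt = [str(as_label(v)) for v in y_true]
    yp = [str(as_label(v)) for v in y_pred]
    if len(yt) != len(yp) or not yt:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    labels = [str(c) for c in CLASS_ORDER]
    return ConfusionMatrix(_sk_confusion(yt, yp, labels=labels))


def one_vs_rest(cm: ConfusionMatrix, c: RhythmLabel) -> dict[str, int]:
    """TP/FP/FN/TN for class ``c`` against the rest."""
    i = list(CLASS_ORDER).index(as_label(c))
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum() - tp)
    fp = int(cm.counts[:, i].sum() - tp)
    tn = cm.total - tp - fn - fp
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def _rate(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return float("nan")
    return 100.0 * num / den


def per_class_metrics(cm: ConfusionMatrix, aucs: dict[RhythmLabel, float] | None = None) -> MetricsReport:
    """Acc/Se/Sp/Pre/F1 per class (percent) plus overall accuracy = trace/total."""
    per: dict[RhythmLabel, ClassMetrics] = {}
    for lab in CLASS_ORDER:
        d = one_vs_rest(cm, lab)
        flags: list[str] = []
        acc = _rate(d["TP"] + d["TN"], cm.total, flags, "acc")
        se = _rate(d["TP"], d["TP"] + d["FN"], flags, "se")
        sp = _rate(d["TN"], d["TN"] + d["FP"], flags, "sp")
        pre = _rate(d["TP"], d["TP"] + d["FP"], flags, "pre")
        if np.isnan(se) or np.isnan(pre) or se + pre == 0:
            flags.append("f1")
            f1 = float("nan")
        else:
            f1 = 2.0 * se * pre / (se + pre)
        per[lab] = ClassMetrics(acc=acc, se=se, sp=sp, pre=pre, f1=f1,
                                auc=None if aucs is None else aucs.get(lab),
                                undefined=flags)
    overall = 100.0 * cm.trace / cm.total
    return MetricsReport(per_class=per, overall_accuracy=overall)


def roc_auc(scores, y_true_binary) -> float:
    """One-vs-rest AUC from per-record scores for the positive class.

    Threshold-sweep/trapezoidal area, identical to the Mann-Whitney rank
    statistic with 0.5 credit per tied pair.  Raises ValueError unless both
    a positive and a negative record are present.
    """
    y = np.asarray(y_true_binary, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    if y.size != s.size or y.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(_sk_auc(y, s))
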