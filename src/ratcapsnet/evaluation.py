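"""Confusion-count bookkeeping and the four classification metrics.

Precision = TP / (TP + FP); Recall = TP / (TP + FN);
F1 = 2 * Prec * Rec / (Prec + Rec); Accuracy = (TP + TN) / total.
A zero denominator yields 0 and the metric's name in ``degenerate`` instead
of an exception, so batch evaluation never aborts.  Multi-class problems are
reduced one-vs-rest per class and macro-averaged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Hashable, Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
    degenerate: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[Hashable, Metrics]
    macro: Metrics


def confusion_from_predictions(truth: Sequence, predicted: Sequence,
                               positive) -> ConfusionCounts:
    """One-vs-rest tally of a label sequence pair."""
    if len(truth) != len(predicted):
        raise ValueError(f"label sequences differ in length: "
                         f"{len(truth)} vs {len(predicted)}")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        t_pos = t == positive
        p_pos = p == positive
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str, degenerate: set[str]) -> float:
    if den == 0:
        degenerate.add(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall, F1, accuracy from one confusion table."""
    degenerate: set[str] = set()
    prec = _ratio(c.tp, c.tp + c.fp, "precision", degenerate)
    rec = _ratio(c.tp, c.tp + c.fn, "recall", degenerate)
    if prec + rec == 0.0:
        degenerate.add("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    acc = _ratio(c.tp + c.tn, c.total, "accuracy", degenerate)
    return Metrics(precision=prec, recall=rec, f1=f1, accuracy=acc,
                   degenerate=frozenset(degenerate))


def multiclass_report(truth: Sequence, predicted: Sequence,
                      labels: Sequence | None = None) -> MetricsReport:
    """One-vs-rest metrics per class plus their macro average."""
    if len(truth) != len(predicted):
        raise ValueError(f"label sequences differ in length: "
                         f"{len(truth)} vs {len(predicted)}")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    per_class = {}
    for label in labels:
        per_class[label] = compute_metrics(
            confusion_from_predictions(truth, predicted, label))
    n = len(per_class)
    macro = Metrics(
        precision=sum(m.precision for m in per_class.values()) / n,
        recall=sum(m.recall for m in per_class.values()) / n,
        f1=sum(m.f1 for m in per_class.values()) / n,
        accuracy=sum(m.accuracy for m in per_class.values()) / n,
        degenerate=frozenset().union(*(m.degenerate
                                       for m in per_class.values())),
    )
    return MetricsReport(per_class=per_class, macro=macro)


def write_metrics_csv(path, report: MetricsReport) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "precision", "recall", "f1", "accuracy",
                         "degenerate"])
        for label, m in report.per_class.items():
            writer.writerow([label, m.precision, m.recall, m.f1, m.accuracy,
                             ";".join(sorted(m.degenerate))])
        mm = report.macro
        writer.writerow(["__macro__", mm.precision, mm.recall, mm.f1,
                         mm.accuracy, ";".join(sorted(mm.degenerate))])


def format_report(report: MetricsReport) -> str:
    lines = [f"{'class':<20} {'prec':>7} {'rec':>7} {'f1':>7} {'acc':>7}"]
    rows = list(report.per_class.items()) + [("macro", report.macro)]
    for label, m in rows:
        flag = " *" if m.degenerate else ""
        lines.append(f"{str(label):<20} {m.precision:7.4f} {m.recall:7.4f} "
                     f"{m.f1:7.4f} {m.accuracy:7.4f}{flag}")
    return "\n".join(lines)
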