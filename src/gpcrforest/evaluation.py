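"""Binary-classifier evaluation: confusion counts, Sn/Sp/Acc/MCC, ROC/AUC,
and mean ± SD aggregation across folds.

Two accuracy variants are always reported, because the two common
conventions genuinely differ on imbalanced data:

* ``acc_weighted`` = (TP+TN)/(TP+FP+TN+FN), the overall correct-classification
  rate (equivalently (Sn·P + Sp·N)/(P+N));
* ``acc_balanced`` = (Sn+Sp)/2, the class-balanced mean.

MCC with a zero marginal is reported as 0 (the standard convention) and
flagged; other metrics with a zero denominator are reported as NaN and
flagged rather than silently coerced.

ROC is computed by sweeping score thresholds from high to low with tied
scores processed as one step; AUC is the trapezoidal area, which equals the
Mann-Whitney U statistic normalised by n₊·n₋ with ties counted 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_METRIC_NAMES = ("sn", "sp", "acc_weighted", "acc_balanced", "mcc", "auc")


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class EvalReport:
    """Metrics for one evaluation (typically one test fold)."""

    confusion: ConfusionMatrix
    sn: float
    sp: float
    acc_weighted: float
    acc_balanced: float
    mcc: float
    auc: float = math.nan
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    undefined: tuple[str, ...] = ()


def confusion(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Confusion counts with +1 as the positive (GPCR) class."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truths, "
                         f"{len(predicted)} predictions")
    if len(truth) == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    tp = fn = tn = fp = 0
    for t, p in zip(truth, predicted):
        if t not in (+1, -1) or p not in (+1, -1):
            raise ValueError(f"labels must be +1 or -1, got truth={t!r} pred={p!r}")
        if t == +1:
            if p == +1:
                tp += 1
            else:
                fn += 1
        else:
            if p == -1:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Sn, Sp, both accuracies and MCC from confusion counts.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); acc_weighted = (TP+TN)/total;
    acc_balanced = (Sn+Sp)/2; MCC = (TP·TN − FP·FN)/√ of the four marginals.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sn = ratio(cm.tp, cm.tp + cm.fn, "sn")
    sp = ratio(cm.tn, cm.tn + cm.fp, "sp")
    acc_w = ratio(cm.tp + cm.tn, cm.total, "acc_weighted")
    acc_b = (sn + sp) / 2
    if math.isnan(acc_b):
        undefined.append("acc_balanced")
    marg = (cm.tp + cm.fn) * (cm.tp + cm.fp) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if marg == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(marg)
    return EvalReport(confusion=cm, sn=sn, sp=sp, acc_weighted=acc_w,
                      acc_balanced=acc_b, mcc=mcc,
                      undefined=tuple(undefined))


def roc_auc(truth: Sequence[int],
            scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve and trapezoidal AUC.

    Returns (auc, points) where points run from (0,0) to (1,1) in
    (false-positive rate, true-positive rate) coordinates, one step per
    distinct score value.
    """
    if len(truth) != len(scores):
        raise ValueError(f"length mismatch: {len(truth)} truths, "
                         f"{len(scores)} scores")
    t = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(t == +1))
    n_neg = int(np.sum(t == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"ROC needs both classes (pos={n_pos}, neg={n_neg})")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # tied scores: one step
            if t_sorted[j] == +1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2
    return auc, points


def evaluate(truth: Sequence[int], predicted: Sequence[int],
             scores: Sequence[float] | None = None) -> EvalReport:
    """Full report from truths, hard predictions, and (optionally) scores."""
    report = metrics(confusion(truth, predicted))
    if scores is not None:
        report.auc, report.roc_points = roc_auc(truth, scores)
    return report


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation."""
    if len(values) < 2:
        raise ValueError("need at least 2 values for mean ± SD")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def aggregate(reports: Sequence[EvalReport]) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample SD) across fold reports."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    out: dict[str, tuple[float, float]] = {}
    for name in _METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        out[name] = mean_sd(vals)
    return out


def format_report_table(reports: Sequence[EvalReport],
                        agg: dict[str, tuple[float, float]] | None = None,
                        sep: str = "\t") -> str:
    """One row per fold plus a mean ± SD row, machine-parseable."""
    header = sep.join(["fold", "TP", "FN", "TN", "FP",
                       "Sn", "Sp", "Acc_weighted", "Acc_balanced", "MCC", "AUC"])
    rows = [header]
    for i, r in enumerate(reports, start=1):
        cm = r.confusion
        rows.append(sep.join(
            [str(i), str(cm.tp), str(cm.fn), str(cm.tn), str(cm.fp)]
            + [format(x, ".4f") for x in (r.sn, r.sp, r.acc_weighted,
                                          r.acc_balanced, r.mcc, r.auc)]
        ))
    if agg is None and len(reports) >= 2:
        agg = aggregate(reports)
    if agg is not None:
        rows.append(sep.join(
            ["mean±SD", "", "", "", ""]
            + [f"{agg[m][0]:.4f}±{agg[m][1]:.4f}" for m in _METRIC_NAMES]
        ))
    return "\n".join(rows)
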