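"""Confusion-matrix bookkeeping and performance measures.

For an L-class confusion matrix M (rows = true class, columns = predicted
class) and a class l, define

    p_l = M[l, l]                      (true positives of l)
    q_l = sum over i != l, j != l      (true negatives of l)
    r_l = column-l sum excluding M[l,l] (false positives of l)
    s_l = row-l sum excluding M[l,l]    (false negatives of l)

and the aggregates p = sum p_l, q = sum q_l, r = sum r_l, s = sum s_l.
The overall sensitivity SE = trace(M) / total (identical to overall
accuracy), and the aggregate multiclass Matthews correlation is

    MCC = (p q - r s) / sqrt((p+r)(p+s)(q+r)(q+s))

with the convention that a zero denominator gives 0. Per-class SP is
precision p_l / (p_l + r_l), SE is recall p_l / (p_l + s_l), and MCC_l the
binary Matthews coefficient of the one-vs-rest reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """L x L counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        L = len(self.classes)
        if self.counts.shape != (L, L):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {L} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


@dataclass(frozen=True)
class ClassQuantities:
    """The (p_l, q_l, r_l, s_l) counts for one class."""

    p: int
    q: int
    r: int
    s: int


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix[i][j] = #{true = classes[i] and predicted = classes[j]}."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class list: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def class_quantities(M: ConfusionMatrix, l: int) -> ClassQuantities:
    """The one-vs-rest counts p_l, q_l, r_l, s_l for class index l."""
    c = M.counts
    p = int(c[l, l])
    r = int(c[:, l].sum() - c[l, l])
    s = int(c[l, :].sum() - c[l, l])
    q = int(c.sum() - p - r - s)
    return ClassQuantities(p=p, q=q, r=r, s=s)


def aggregate_quantities(M: ConfusionMatrix) -> ClassQuantities:
    """Sums of p_l, q_l, r_l, s_l over all classes."""
    qs = [class_quantities(M, l) for l in range(len(M.classes))]
    return ClassQuantities(
        p=sum(x.p for x in qs),
        q=sum(x.q for x in qs),
        r=sum(x.r for x in qs),
        s=sum(x.s for x in qs),
    )


def overall_se(M: ConfusionMatrix) -> float:
    """trace(M) / total — the overall sensitivity, identical to overall accuracy."""
    if M.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(M.counts)) / M.total


def _mcc(p: float, q: float, r: float, s: float) -> float:
    denom = (p + r) * (p + s) * (q + r) * (q + s)
    if denom == 0:
        return 0.0
    return (p * q - r * s) / math.sqrt(denom)


def multiclass_mcc(M: ConfusionMatrix) -> float:
    """Aggregate multiclass Matthews correlation from the pooled p, q, r, s."""
    if M.total == 0:
        raise ValueError("empty confusion matrix")
    agg = aggregate_quantities(M)
    return _mcc(agg.p, agg.q, agg.r, agg.s)


def per_class_metrics(M: ConfusionMatrix) -> pd.DataFrame:
    """Per-class table: location, size, SP (precision), SE (recall), MCC.

    A class never predicted has undefined SP; a class never observed has
    undefined SE. Both report as 0.0 with the ``undefined`` column flagging
    which measure degenerated.
    """
    if M.total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for l, name in enumerate(M.classes):
        cq = class_quantities(M, l)
        undefined = []
        if cq.p + cq.r == 0:
            sp = 0.0
            undefined.append("SP")
        else:
            sp = cq.p / (cq.p + cq.r)
        if cq.p + cq.s == 0:
            se = 0.0
            undefined.append("SE")
        else:
            se = cq.p / (cq.p + cq.s)
        rows.append(
            {
                "location": name,
                "size": cq.p + cq.s,
                "SP": sp,
                "SE": se,
                "MCC": _mcc(cq.p, cq.q, cq.r, cq.s),
                "undefined": ",".join(undefined),
            }
        )
    return pd.DataFrame(rows)


def write_report(M: ConfusionMatrix, path) -> None:
    """Write the per-class table plus overall accuracy as TSV."""
    table = per_class_metrics(M)
    with open(path, "w") as fh:
        table.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        fh.write(f"# overall_accuracy\t{overall_se(M):.4f}\n")
        fh.write(f"# overall_mcc\t{multiclass_mcc(M):.4f}\n")
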