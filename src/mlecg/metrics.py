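"""Per-class one-vs-rest confusion counts and ACC/SE/SP.

For each class c the four counts are taken one-vs-rest over the full test
set: TP (label c, predicted c), FP (label != c, predicted c), FN (label c,
predicted != c), TN (neither).  From these,

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SE  = TP / (TP + FN)        (sensitivity / recall; 1 - FNR)
    SP  = TN / (TN + FP)        (specificity)

all reported as percentages, displayed half-up to 2 decimals with full
precision retained internally.  SE is undefined when a class has no positive
samples (TP + FN = 0) and SP when it has no negatives; undefined values are
flagged rather than propagated as NaN surprises.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for f in ("tp", "tn", "fp", "fn"):
            v = getattr(self, f)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f} must be a non-negative integer")
            setattr(self, f, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassMetrics:
    acc: float
    se: float | None    # None when undefined (no positive samples)
    sp: float | None    # None when undefined (no negative samples)

    def rounded(self) -> tuple:
        return tuple(None if v is None else round2(v)
                     for v in (self.acc, self.se, self.sp))


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def confusion_per_class(predictions, labels, n_classes: int) -> list[ConfusionCounts]:
    """One-vs-rest TP/TN/FP/FN for every class."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"predictions ({predictions.shape}) and labels ({labels.shape}) "
            "must have equal length")
    if predictions.size and (min(predictions.min(), labels.min()) < 0
                             or max(predictions.max(), labels.max()) >= n_classes):
        raise ValueError(f"values must lie in [0, {n_classes})")
    out = []
    for c in range(n_classes):
        p = predictions == c
        t = labels == c
        out.append(ConfusionCounts(
            tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
            fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t))))
    return out


def compute_metrics(c: ConfusionCounts) -> ClassMetrics:
    """ACC/SE/SP (percent) from one class's counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (c.tp + c.tn) / c.total
    se = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return ClassMetrics(acc=acc, se=se, sp=sp)


def validate_counts(counts: list[ConfusionCounts]) -> list[int]:
    """Indices of classes whose four counts do not sum to the common total.

    One-vs-rest counts over a single evaluation set must all sum to the same
    sample count; a mismatch indicates an inconsistent table.
    """
    totals = [c.total for c in counts]
    if not totals:
        return []
    best = max(totals.count(t) for t in totals)
    common = next(t for t in totals if totals.count(t) == best)
    return [i for i, t in enumerate(totals) if t != common]


def evaluation_report(predictions, labels, n_classes: int,
                      class_names=None) -> pd.DataFrame:
    """Per-class table (TP, TN, FP, FN, ACC, SE, SP) plus a macro-average row.

    The macro row averages each metric over the classes where it is defined.
    """
    counts = confusion_per_class(predictions, labels, n_classes)
    names = class_names or [f"class_{i}" for i in range(n_classes)]
    rows = []
    for name, c in zip(names, counts):
        m = compute_metrics(c)
        acc, se, sp = m.rounded()
        rows.append({"class": name, "TP": c.tp, "TN": c.tn, "FP": c.fp,
                     "FN": c.fn, "ACC": acc, "SE": se, "SP": sp})
    df = pd.DataFrame(rows)
    macro = {"class": "macro", "TP": "", "TN": "", "FP": "", "FN": ""}
    for col in ("ACC", "SE", "SP"):
        vals = [r[col] for r in rows if r[col] is not None]
        macro[col] = round2(float(np.mean(vals))) if vals else None
    return pd.concat([df, pd.DataFrame([macro])], ignore_index=True)
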