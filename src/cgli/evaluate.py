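"""FOV-masked segmentation evaluation: confusion counts, Acc/Se/Sp, Dice.

Fundus cameras image a circular field of view (FOV) surrounded by a dark
aperture border that any method trivially classifies; all counts here are
therefore restricted to pixels inside a FOV mask.  Sensitivity is the
fraction of true vessel pixels recovered, specificity the fraction of true
background kept, accuracy the overall agreement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "confusion_counts",
    "metrics",
    "dice",
    "EvalReport",
    "mean_reports",
    "pooled_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A ratio's denominator is zero (e.g. Se with no positive pixels)."""


def _binary(a, name):
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array")
    return a.astype(bool)


def confusion_counts(pred, truth, fov=None):
    """(tp, fp, tn, fn) counted over the pixels where ``fov`` is true.

    ``fov=None`` means the whole grid.  An empty FOV is an error: every
    metric downstream would be undefined.
    """
    pred = _binary(pred, "pred")
    truth = _binary(truth, "truth")
    fov = np.ones_like(pred) if fov is None else _binary(fov, "fov")
    if not (pred.shape == truth.shape == fov.shape):
        raise ValueError("pred, truth and fov must share one shape")
    if not fov.any():
        raise ValueError("FOV mask is empty")
    p, t = pred[fov], truth[fov]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    tn = int(np.count_nonzero(~p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int):
    """(acc, se, sp) from confusion counts, exact rational arithmetic.

        Acc = (TP+TN)/N,  Se = TP/(TP+FN),  Sp = TN/(TN+FP),
        N = TP+FP+TN+FN.

    Raises :class:`UndefinedMetricError` on a zero denominator rather than
    silently returning 0 — silent zeros would corrupt dataset averages.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n = tp + fp + tn + fn
    if n == 0:
        raise UndefinedMetricError("no pixels counted (N = 0)")
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive pixels")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative pixels")
    acc = float(Fraction(tp + tn, n))
    se = float(Fraction(tp, tp + fn))
    sp = float(Fraction(tn, tn + fp))
    return acc, se, sp


def dice(pred, truth, fov=None) -> float:
    """Dice overlap 2*TP / (2*TP + FP + FN) inside the FOV.

    Defined as 1.0 when both masks are empty within the FOV (identical).
    """
    tp, fp, tn, fn = confusion_counts(pred, truth, fov)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return float(Fraction(2 * tp, denom))


@dataclass
class EvalReport:
    """Confusion counts and FOV-restricted Acc/Se/Sp for one image."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    se: float
    sp: float
    n: int

    @classmethod
    def from_masks(cls, pred, truth, fov=None) -> "EvalReport":
        tp, fp, tn, fn = confusion_counts(pred, truth, fov)
        acc, se, sp = metrics(tp, fp, tn, fn)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, se=se, sp=sp,
                   n=tp + fp + tn + fn)

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")

    def to_text(self, path) -> None:
        """Flat ``key value`` lines, one metric per line."""
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k} {v}\n")


def mean_reports(reports) -> dict:
    """Unweighted per-image mean of acc/se/sp (the default dataset average)."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to average")
    return {
        k: float(np.mean([getattr(r, k) for r in reports]))
        for k in ("acc", "se", "sp")
    }


def pooled_report(reports) -> "EvalReport":
    """Alternative dataset summary: pool the counts, then compute metrics."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to pool")
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    tn = sum(r.tn for r in reports)
    fn = sum(r.fn for r in reports)
    acc, se, sp = metrics(tp, fp, tn, fn)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, se=se, sp=sp,
                      n=tp + fp + tn + fn)
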