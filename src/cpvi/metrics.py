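"""Detection scoring against gold-standard labels, and inter-rater agreement.

The headline score is the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
a balanced summary of the 2x2 confusion matrix in [-1, 1]; a zero factor in
the denominator yields MCC = 0 by the usual convention.  Sensitivity,
specificity, predictive values and accuracy are reported alongside, with 0/0
ratios left undefined (NaN) and excluded from aggregation.  Fleiss' kappa
quantifies chance-corrected agreement among >= 2 raters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    mcc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def confusion(pred: Sequence[int], gold: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix of binary predictions against labels."""
    p = np.asarray(pred)
    g = np.asarray(gold)
    if p.shape != g.shape or p.ndim != 1:
        raise InputError(f"length mismatch: {p.shape} vs {g.shape}")
    if not (np.isin(p, (0, 1)).all() and np.isin(g, (0, 1)).all()):
        raise InputError("labels must be binary (0/1)")
    p = p.astype(bool)
    g = g.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is zero."""
    if c.total == 0:
        raise InputError("empty confusion counts")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def performance(c: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy and MCC from the counts."""
    if c.total == 0:
        raise InputError("empty confusion counts")
    return PerformanceMetrics(
        mcc=mcc(c),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=(c.tp + c.tn) / c.total,
    )


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for categorical ratings, subjects x raters.

    ``ratings[i, j]`` is the category rater j assigned to subject i (any
    hashable values; typically 0/1).  Every subject must be rated by the same
    number of raters.
    """
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

    arr = np.asarray(ratings)
    if arr.ndim != 2:
        raise InputError("ratings must be a subjects x raters matrix")
    n_subjects, n_raters = arr.shape
    if n_subjects < 2 or n_raters < 2:
        raise InputError("need >= 2 subjects and >= 2 raters")
    if not np.isfinite(arr.astype(float)).all():
        raise InputError("missing ratings: every subject needs the same rater count")
    table, _ = aggregate_raters(arr)
    if np.any(table.sum(axis=1) != n_raters):
        raise InputError("variable rater count per subject")
    if table.shape[1] < 2:
        return 1.0  # a single category used throughout: perfect agreement
    return float(_sm_fleiss(table, method="fleiss"))


def stratified_performance(pred: Sequence[int], gold: Sequence[int],
                           strata: Sequence) -> dict:
    """Performance within each stratum (e.g. ventilation mode) separately."""
    p = np.asarray(pred)
    g = np.asarray(gold)
    s = np.asarray(strata)
    if not (p.shape == g.shape == s.shape):
        raise InputError("pred, gold and strata must align")
    out = {}
    for key in pd_unique(s):
        mask = s == key
        if not mask.any():
            logger.warning("stratum %r empty; omitted", key)
            continue
        out[key] = performance(confusion(p[mask], g[mask]))
    return out


def pd_unique(values: np.ndarray) -> list:
    """Unique values in first-appearance order."""
    seen: dict = {}
    for v in values.tolist():
        seen.setdefault(v, None)
    return list(seen)
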