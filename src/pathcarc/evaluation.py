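"""ROC evaluation, operating points with confusion lists, dose-response slopes."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledScores",
    "OperatingPoint",
    "DoseSeries",
    "roc_auc",
    "roc_points",
    "operating_point",
    "dose_slope",
]


@dataclass
class LabeledScores:
    """Continuous predictions paired with binary carcinogenicity labels."""

    ids: Sequence[str]
    scores: Sequence[float]
    labels: Sequence[str]  # 'positive' | 'negative'

    def __post_init__(self):
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        bad = set(self.labels) - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n_positive(self) -> int:
        return sum(1 for x in self.labels if x == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for x in self.labels if x == "negative")

    def _check_both_classes(self):
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError("need at least one positive and one negative item")


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    false_positive_ids: list
    false_negative_ids: list


@dataclass
class DoseSeries:
    """Predicted carcinogenicity values over an increasing dose ladder."""

    chemical_id: str
    doses: Sequence[float]
    predicted_z: Sequence[float]
    dose_unit: float = 1.0  # slope is reported per this many dose units

    def __post_init__(self):
        if len(self.doses) < 3:
            raise ValueError("a dose series needs at least 3 points")
        if len(self.doses) != len(self.predicted_z):
            raise ValueError("doses and predictions must have equal length")
        d = np.asarray(self.doses, dtype=float)
        if not (np.diff(d) > 0).all():
            raise ValueError("doses must be strictly increasing")


def roc_auc(data: LabeledScores) -> float:
    """Tie-aware Mann-Whitney AUC.

    Probability a random positive outscores a random negative, with ties
    counted 1/2 — equal to the trapezoidal area under the tie-aware ROC.
    """
    data._check_both_classes()
    scores = np.asarray(data.scores, dtype=float)
    pos = np.array([lab == "positive" for lab in data.labels])
    ranks = stats.rankdata(scores)  # average ranks handle ties exactly
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(data: LabeledScores) -> pd.DataFrame:
    """ROC vertices: one row per candidate threshold (call positive if
    score >= threshold), including the all-negative extreme."""
    data._check_both_classes()
    scores = np.asarray(data.scores, dtype=float)
    pos = np.array([lab == "positive" for lab in data.labels])
    thresholds = np.concatenate((np.unique(scores)[::-1], [math.inf]))
    rows = []
    for thr in thresholds:
        called = scores >= thr
        tp = int((called & pos).sum())
        fp = int((called & ~pos).sum())
        fn = int((~called & pos).sum())
        tn = int((~called & ~pos).sum())
        rows.append(
            {
                "threshold": thr,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
            }
        )
    return pd.DataFrame(rows)


def operating_point(data: LabeledScores, spec_range: tuple = (0.56, 0.75)) -> OperatingPoint:
    """Best ROC vertex within a specificity window.

    Among thresholds whose specificity lies inside ``spec_range``
    (inclusive), pick the one maximizing sensitivity, breaking ties toward
    higher specificity; report false positives/negatives by id.
    """
    lo, hi = spec_range
    pts = roc_points(data)
    inside = pts[(pts.specificity >= lo) & (pts.specificity <= hi)]
    if inside.empty:
        achievable = sorted(pts.specificity.unique())
        raise ValueError(
            f"no ROC vertex with specificity in [{lo}, {hi}]; "
            f"achievable specificities: {achievable}"
        )
    best = inside.sort_values(
        ["sensitivity", "specificity"], ascending=False, kind="stable"
    ).iloc[0]
    thr = float(best.threshold)
    scores = np.asarray(data.scores, dtype=float)
    pos = np.array([lab == "positive" for lab in data.labels])
    called = scores >= thr
    fp_ids = [i for i, c, p in zip(data.ids, called, pos) if c and not p]
    fn_ids = [i for i, c, p in zip(data.ids, called, pos) if not c and p]
    return OperatingPoint(
        thr, float(best.sensitivity), float(best.specificity), fp_ids, fn_ids
    )


def dose_slope(series: DoseSeries) -> tuple:
    """OLS slope of predicted z on dose, with a one-sided (positive-slope) p.

    The slope is reported per ``series.dose_unit`` dose units; the p-value
    is the upper tail of the slope's t statistic on n - 2 degrees of
    freedom (perfect positive fits give p -> 0, flat series p = 0.5).
    """
    x = np.asarray(series.doses, dtype=float) / series.dose_unit
    y = np.asarray(series.predicted_z, dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero dose variance")
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx  # exact 0 for constant y (yc is exactly 0)
    resid = yc - slope * xc
    sse = float(resid @ resid)
    if sse == 0.0:
        p = 0.0 if slope > 0 else (1.0 if slope < 0 else 0.5)
        return float(slope), p
    se = math.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    return float(slope), float(stats.t.sf(t, df=n - 2))
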