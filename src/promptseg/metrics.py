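"""Evaluation metrics for binary segmentation.

Ten per-image metrics: IoU, Dice, F1, mAP (pixelwise average precision),
Hausdorff distance, Cohen's kappa, specificity, recall, precision and
pixel accuracy.  All count-ratio metrics follow one zero-denominator
convention: a ratio whose denominator is 0 is 1.0 when the corresponding
error count is also 0 (nothing to find, nothing found wrong), else 0.0.

Cohen's kappa is computed from the 2x2 pixel contingency table and is
bounded above by 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .losses import hausdorff_distance

METRIC_NAMES = ("iou", "dice", "f1", "map", "hd", "kappa", "specificity",
                "recall", "precision", "pixel_accuracy")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    iou: float
    dice: float
    f1: float
    map: float
    hd: float
    kappa: float
    specificity: float
    recall: float
    precision: float
    pixel_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixelwise 2x2 contingency counts between two binary masks."""
    p = np.asarray(getattr(pred, "values", pred)).astype(bool)
    g = np.asarray(getattr(gt, "values", gt)).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, denom: int, error_count: int) -> float:
    if denom == 0:
        return 1.0 if error_count == 0 else 0.0
    return num / denom


def cohens_kappa(c: ConfusionCounts) -> float:
    """Chance-corrected pixel agreement; always <= 1."""
    n = c.total
    if n == 0:
        raise ValueError("kappa undefined for empty masks")
    p_o = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.fn + c.tn) / n) * ((c.fp + c.tn) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        # both raters constant; agreement is perfect or degenerate
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def average_precision(prob: np.ndarray, gt: np.ndarray) -> float:
    """Area under the pixelwise precision-recall curve (step interpolation).

    Sweeps every unique score as a threshold, from high to low.  For an
    empty ground truth: 1.0 if the prediction scores are all zero, else 0.0
    (no positives rankable).
    """
    scores = np.asarray(prob, dtype=float).ravel()
    labels = np.asarray(getattr(gt, "values", gt)).astype(bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("probability map and ground truth differ in size")
    n_pos = int(labels.sum())
    if n_pos == 0:
        return 1.0 if np.all(scores == 0) else 0.0
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp_cum = np.cumsum(sorted_labels)
    ranks = np.arange(1, len(scores) + 1)
    # evaluate P/R only at threshold boundaries (last index of each score tie)
    boundary = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    precision = tp_cum[boundary] / ranks[boundary]
    recall = tp_cum[boundary] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def compute_metrics(prob: np.ndarray, gt: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """All ten metrics from a probability map and a binary ground truth."""
    from .decoder import binarize

    prob = np.asarray(prob, dtype=float)
    g = np.asarray(getattr(gt, "values", gt)).astype(np.uint8)
    if prob.shape != g.shape:
        raise ValueError(f"shapes differ: {prob.shape} vs {g.shape}")
    pred = binarize(prob, threshold).values
    c = confusion_counts(pred, g)
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp + c.fn)
    return MetricReport(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, c.fp + c.fn),
        dice=dice,
        f1=dice,  # identical to Dice for binary masks
        map=average_precision(prob, g),
        hd=hausdorff_distance(pred, g),
        kappa=cohens_kappa(c),
        specificity=_ratio(c.tn, c.tn + c.fp, c.fp),
        recall=_ratio(c.tp, c.tp + c.fn, c.fn),
        precision=_ratio(c.tp, c.tp + c.fp, c.fp),
        pixel_accuracy=_ratio(c.tp + c.tn, c.total, c.fp + c.fn),
    )


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Unweighted per-metric mean; the mean of per-class APs is the 'm' in mAP."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    return MetricReport(**{
        name: float(np.mean([getattr(r, name) for r in reports]))
        for name in METRIC_NAMES})


def report_table(reports: list[MetricReport]) -> "object":
    """Per-sample rows plus mean and std, as a pandas DataFrame."""
    import pandas as pd

    rows = [r.as_dict() for r in reports]
    df = pd.DataFrame(rows)
    df.loc["mean"] = df.mean()
    df.loc["std"] = df.iloc[:-1].std(ddof=1) if len(rows) > 1 else 0.0
    return df
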