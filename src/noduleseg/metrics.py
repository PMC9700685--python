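"""Overlap metrics for binary segmentation masks.

For a ground-truth mask G and predicted mask P (pixel sets):

    DSC         = 2|G∩P| / (|G|+|P|)      Dice similarity coefficient
    IoU         = |G∩P| / |G∪P|           Jaccard index
    sensitivity = |G∩P| / |G|             recall of nodule pixels
    precision   = |G∩P| / |P|             purity of predicted pixels

Degenerate conventions (the formulas are otherwise 0/0): if both masks
are empty every metric is 1; an empty prediction against a non-empty
ground truth scores 0 precision, and vice versa for sensitivity.  DSC is
both 2·IoU/(1+IoU) and the harmonic mean of sensitivity and precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["MaskPair", "SegmentationMetrics", "dsc", "iou", "sensitivity",
           "precision", "evaluate_pair", "batch_report", "report_to_files"]


@dataclass(frozen=True)
class MaskPair:
    gt: np.ndarray
    pred: np.ndarray

    def __post_init__(self):
        gt = np.asarray(self.gt)
        pred = np.asarray(self.pred)
        if gt.shape != pred.shape:
            raise ValueError("gt and pred shapes differ")
        for m in (gt, pred):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")
        object.__setattr__(self, "gt", gt.astype(bool))
        object.__setattr__(self, "pred", pred.astype(bool))

    @property
    def counts(self):
        """(|G|, |P|, |G∩P|) pixel counts."""
        return (int(self.gt.sum()), int(self.pred.sum()),
                int((self.gt & self.pred).sum()))


@dataclass(frozen=True)
class SegmentationMetrics:
    dsc: float
    iou: float
    sensitivity: float
    precision: float
    n_gt: int
    n_pred: int
    n_intersection: int


def _as_pair(pair, pred=None) -> MaskPair:
    if pred is not None:
        return MaskPair(pair, pred)
    return pair if isinstance(pair, MaskPair) else MaskPair(*pair)


def dsc(pair, pred=None) -> float:
    g, p, i = _as_pair(pair, pred).counts
    return 1.0 if g + p == 0 else 2.0 * i / (g + p)


def iou(pair, pred=None) -> float:
    g, p, i = _as_pair(pair, pred).counts
    union = g + p - i
    return 1.0 if union == 0 else i / union


def sensitivity(pair, pred=None) -> float:
    g, _, i = _as_pair(pair, pred).counts
    return 1.0 if g == 0 else i / g


def precision(pair, pred=None) -> float:
    g, p, i = _as_pair(pair, pred).counts
    if p == 0:
        return 1.0 if g == 0 else 0.0
    return i / p


def evaluate_pair(pair, pred=None) -> SegmentationMetrics:
    pair = _as_pair(pair, pred)
    g, p, i = pair.counts
    return SegmentationMetrics(dsc(pair), iou(pair), sensitivity(pair),
                               precision(pair), g, p, i)


def batch_report(pairs) -> dict:
    """Aggregate metrics over mask pairs.

    Returns macro averages (per-sample metrics averaged, the headline
    numbers), pooled micro variants (counts summed over the batch before
    the formulas are applied), and the per-sample table.
    """
    pairs = [_as_pair(p) for p in pairs]
    if not pairs:
        raise ValueError("batch_report needs at least one mask pair")
    per_sample = [evaluate_pair(p) for p in pairs]
    macro = {k: float(np.mean([getattr(m, k) for m in per_sample]))
             for k in ("dsc", "iou", "sensitivity", "precision")}
    g = sum(m.n_gt for m in per_sample)
    p = sum(m.n_pred for m in per_sample)
    i = sum(m.n_intersection for m in per_sample)
    micro = {
        "dsc": 1.0 if g + p == 0 else 2.0 * i / (g + p),
        "iou": 1.0 if g + p - i == 0 else i / (g + p - i),
        "sensitivity": 1.0 if g == 0 else i / g,
        "precision": (1.0 if g == 0 else 0.0) if p == 0 else i / p,
    }
    return {"macro": macro, "micro": micro,
            "per_sample": per_sample, "n": len(per_sample)}


def report_to_files(report: dict, out_dir, ids=None):
    """Write the per-sample table as CSV and the aggregates as JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [asdict(m) for m in report["per_sample"]]
    df = pd.DataFrame(rows)
    df.insert(0, "id", ids if ids is not None else range(len(rows)))
    df.to_csv(out / "metrics_per_sample.csv", index=False)
    agg = {"macro": report["macro"], "micro": report["micro"],
           "n": report["n"]}
    (out / "metrics.json").write_text(json.dumps(agg, indent=2))
    return out / "metrics.json"
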