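"""Segmentation evaluation: overlap metrics from confusion counts and the
average symmetric surface distance (ASSD) from boundary distances.

All overlap metrics derive from pixel-level confusion counts between a
predicted binary mask A and a ground-truth mask B:

    Dice        = 2*TP / (2*TP + FP + FN)
    Jaccard     = TP / (TP + FP + FN)
    VOE         = 1 - Jaccard
    Accuracy    = (TP + TN) / total
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

ASSD averages, symmetrically over both boundaries, the Euclidean distance
from each boundary pixel of one mask to the nearest boundary pixel of the
other.  Boundary pixels are foreground pixels with at least one background
4-neighbour; the image border counts as background.  Distances are in
pixels, or millimetres when a pixel spacing is supplied.

Empty-mask policy: if both masks are empty the overlap is perfect
(Dice = Jaccard = 1) and ASSD is undefined (reported as NaN); if only the
prediction is empty, Dice = 0 and the case is flagged as a
non-segmentation.  Sensitivity is undefined (NaN) when the ground truth is
empty, specificity when it fills the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

METRIC_NAMES = ("dice", "assd", "jaccard", "voe", "accuracy", "sensitivity", "specificity")


@dataclass
class MaskPair:
    """Predicted mask A and ground-truth mask B with optional spacing (mm)."""

    A: np.ndarray
    B: np.ndarray
    spacing: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.A = _as_binary(self.A, "A")
        self.B = _as_binary(self.B, "B")
        if self.A.shape != self.B.shape:
            raise ValueError(f"mask extents differ: {self.A.shape} vs {self.B.shape}")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask {name} is not binary; values found: {vals[:8]}")
        mask = mask.astype(bool)
    return mask


def confusion(pair: MaskPair) -> ConfusionCounts:
    """Exact pixel confusion counts between prediction A and truth B."""
    a, b = pair.A, pair.B
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    tn = a.size - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def overlap_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """The six overlap-family metrics from confusion counts.

    Undefined ratios (empty denominators) are reported as NaN rather than
    coerced to 0, except the both-empty case where perfect agreement gives
    Dice = Jaccard = 1.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total <= 0:
        raise ValueError("empty masks: zero total pixel count")
    if tp + fp + fn == 0:  # both masks empty: perfect agreement
        dice = jaccard = 1.0
    else:
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
        jaccard = tp / (tp + fp + fn)
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    specificity = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return {
        "dice": dice,
        "jaccard": jaccard,
        "voe": 1.0 - jaccard,
        "accuracy": (tp + tn) / counts.total,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: foreground with a background 4-neighbour (border included)."""
    mask = _as_binary(mask, "mask")
    if not mask.any():
        return np.zeros_like(mask)
    interior = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1),
                                  border_value=0)
    return mask & ~interior


def assd(pair: MaskPair) -> float:
    """Average symmetric surface distance between the two mask boundaries.

    NaN when either mask is empty (no surface to measure).  Euclidean, in
    pixel units unless the pair carries a spacing (then mm).
    """
    if not pair.A.any() or not pair.B.any():
        return float("nan")
    da = boundary(pair.A)
    db = boundary(pair.B)
    sampling = pair.spacing if pair.spacing is not None else (1.0, 1.0)
    # distance-to-nearest-boundary fields via exact Euclidean distance transform
    dist_to_a = ndi.distance_transform_edt(~da, sampling=sampling)
    dist_to_b = ndi.distance_transform_edt(~db, sampling=sampling)
    sum_b_to_a = float(dist_to_a[db].sum())
    sum_a_to_b = float(dist_to_b[da].sum())
    n = int(np.count_nonzero(da)) + int(np.count_nonzero(db))
    return (sum_a_to_b + sum_b_to_a) / n


@dataclass
class CaseReport:
    """Per-case metric values plus failure flags."""

    case_id: str
    metrics: Dict[str, float]
    non_segmentation: bool = False   # truth has tumor, prediction empty


@dataclass
class MetricReport:
    """Aggregate mean ± population std over cases, per metric."""

    cases: List[CaseReport]
    mean: Dict[str, float]
    std: Dict[str, float]
    grouping: str = "slice"

    def to_frame(self):
        import pandas as pd

        rows = [{"case_id": c.case_id, **c.metrics, "non_segmentation": c.non_segmentation}
                for c in self.cases]
        return pd.DataFrame(rows)

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"metric": m, "mean": self.mean.get(m, float("nan")),
              "std": self.std.get(m, float("nan"))} for m in METRIC_NAMES]
        )


def evaluate_pair(pair: MaskPair, case_id: str = "") -> CaseReport:
    """All seven metrics for one prediction/truth pair."""
    counts = confusion(pair)
    m = overlap_metrics(counts)
    if not pair.A.any() and pair.B.any():
        m["dice"] = 0.0
        m["jaccard"] = 0.0
        m["voe"] = 1.0
        flag = True
    else:
        flag = False
    m["assd"] = assd(pair)
    return CaseReport(case_id=case_id, metrics=m, non_segmentation=flag)


def aggregate(pairs: Sequence[MaskPair],
              case_ids: Optional[Sequence[str]] = None,
              grouping: str = "slice",
              volume_ids: Optional[Sequence] = None) -> MetricReport:
    """Mean ± population std of the seven metrics over cases.

    ``grouping='slice'`` treats every pair as one case; ``'volume'`` stacks
    all slices of a volume into a single 3-D-indexed case whose counts are
    pooled before the metrics are computed (ASSD pools the per-slice 2-D
    boundaries).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no cases to aggregate")
    if case_ids is None:
        case_ids = [str(i) for i in range(len(pairs))]
    if grouping == "volume":
        if volume_ids is None or len(volume_ids) != len(pairs):
            raise ValueError("volume grouping requires one volume id per pair")
        order = {v: i for i, v in enumerate(dict.fromkeys(volume_ids))}
        grouped: Dict[object, List[MaskPair]] = {}
        for p, v in zip(pairs, volume_ids):
            grouped.setdefault(v, []).append(p)
        cases = []
        for v in sorted(grouped, key=lambda v: order[v]):
            ps = grouped[v]
            a = np.stack([p.A for p in ps])
            b = np.stack([p.B for p in ps])
            cases.append(_evaluate_stack(a, b, ps[0].spacing, str(v)))
    else:
        cases = [evaluate_pair(p, str(cid)) for p, cid in zip(pairs, case_ids)]
    mean, std = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([c.metrics[m] for c in cases], dtype=float)
        vals = vals[~np.isnan(vals)]
        mean[m] = float(vals.mean()) if vals.size else float("nan")
        std[m] = float(vals.std(ddof=0)) if vals.size else float("nan")
    return MetricReport(cases=cases, mean=mean, std=std, grouping=grouping)


def _evaluate_stack(a: np.ndarray, b: np.ndarray, spacing, case_id: str) -> CaseReport:
    """Volume case: pooled confusion counts and pooled per-slice 2-D boundaries."""
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    tn = a.size - tp - fp - fn
    m = overlap_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
    if not a.any() and b.any():
        m["dice"], m["jaccard"], m["voe"] = 0.0, 0.0, 1.0
        flag = True
    else:
        flag = False
    # pooled 2-D boundary distances across slices
    sums, counts_ = 0.0, 0
    per_slice = [assd(MaskPair(sa, sb, spacing)) for sa, sb in zip(a, b)
                 if sa.any() and sb.any()]
    if per_slice:
        bsizes = [int(np.count_nonzero(boundary(sa))) + int(np.count_nonzero(boundary(sb)))
                  for sa, sb in zip(a, b) if sa.any() and sb.any()]
        sums = sum(v * n for v, n in zip(per_slice, bsizes))
        counts_ = sum(bsizes)
    m["assd"] = sums / counts_ if counts_ else float("nan")
    return CaseReport(case_id=case_id, metrics=m, non_segmentation=flag)
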