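"""Registration and classification metrics, threshold selection, cohort summaries.

Registration quality is quantified with the Dice overlap coefficient and the
symmetric Hausdorff distance between structure surfaces (physical units,
anisotropic spacing respected), compared before (moving vs fixed) and after
(warped vs fixed) registration. Classification is evaluated with ROC/AUC,
accuracy, sensitivity, specificity and F1 = 2TP/(2TP+FP+FN) with ATS as the
positive class, plus threshold selection by the Youden index or by
balancing sensitivity against specificity. Cohort-level strategy counts are
aggregated into totals and rounded percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient ``2|a∩b| / (|a|+|b|)``; 1.0 when both masks are empty."""
    a = np.asarray(a) > 0.5
    b = np.asarray(b) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def hausdorff(a: np.ndarray, b: np.ndarray,
              spacing: Sequence[float] = (1.0, 1.0, 1.0),
              percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance (mm) between surface voxel sets.

    ``percentile=100`` gives the classical maximum; ``percentile=95`` the
    robust variant. Distances are Euclidean in physical units.
    """
    a = np.asarray(a) > 0.5
    b = np.asarray(b) > 0.5
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance undefined for empty masks")
    sa, sb = _surface(a), _surface(b)
    # distance map to the nearest surface voxel of the other mask
    da = ndimage.distance_transform_edt(~sb, sampling=spacing)[sa]
    db = ndimage.distance_transform_edt(~sa, sampling=spacing)[sb]
    if percentile >= 100.0:
        return float(max(da.max(), db.max()))
    return float(max(np.percentile(da, percentile), np.percentile(db, percentile)))


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Confusion-matrix counts with ATS (replan) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalMetrics:
    """Headline classification metrics; undefined ratios are NaN."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float


def _check_labels_probs(labels, probs) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray([int(v) for v in labels])
    p = np.asarray(probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, p


def roc_auc(labels: Sequence[int], probs: Sequence[float]
            ) -> Tuple[float, np.ndarray]:
    """AUC by the trapezoidal rule, plus the (FPR, TPR) curve points.

    Equals the Mann-Whitney pairwise concordance with ties counted 1/2.
    Requires both classes to be present.
    """
    y, p = _check_labels_probs(labels, probs)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC requires both classes")
    order = np.argsort(-p, kind="stable")
    ys = y[order]
    ps = p[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # one operating point per distinct threshold (handle tied scores)
    distinct = np.r_[np.nonzero(np.diff(ps))[0], ps.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def confusion_at_threshold(labels: Sequence[int], probs: Sequence[float],
                           threshold: float) -> Tuple[ConfusionCounts, EvalMetrics]:
    """Counts and metrics under the strict rule: predict ATS iff p > threshold.

    Ratios with empty denominators (e.g. sensitivity with no positives) are
    reported as NaN with a warning.
    """
    y, p = _check_labels_probs(labels, probs)
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator)", stacklevel=3)
            return math.nan
        return num / den

    try:
        auc = roc_auc(y, p)[0]
    except ValueError:
        auc = math.nan
    metrics = EvalMetrics(
        auc=auc,
        accuracy=(tp + tn) / counts.total,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    )
    return counts, metrics


def select_threshold(labels: Sequence[int], probs: Sequence[float],
                     criterion: str = "balance") -> float:
    """Operating-point selection over midpoints of sorted unique scores.

    ``youden`` maximizes TPR - FPR; ``balance`` minimizes
    |sensitivity - specificity|. Ties break toward the larger threshold.
    """
    y, p = _check_labels_probs(labels, probs)
    if len(set(y.tolist())) < 2:
        raise ValueError("threshold selection requires both classes")
    uniq = np.unique(p)
    candidates = np.r_[uniq[0] - 0.5, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 0.5]
    best_thr, best_score = None, -np.inf
    for thr in candidates:
        _, m = confusion_at_threshold(y, p, thr)
        if criterion == "youden":
            score = m.sensitivity - (1.0 - m.specificity)
        elif criterion == "balance":
            score = -abs(m.sensitivity - m.specificity)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if math.isnan(score):
            continue
        if score >= best_score:  # >= breaks ties toward larger thresholds
            best_score, best_thr = score, float(thr)
    return best_thr


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-patient (ATP, ATS) fraction counts plus totals and proportions."""

    per_patient: List[Tuple[int, int]]
    total_atp: int
    total_ats: int

    @property
    def total(self) -> int:
        return self.total_atp + self.total_ats

    @property
    def proportion_atp(self) -> float:
        return self.total_atp / self.total

    @property
    def proportion_ats(self) -> float:
        return self.total_ats / self.total

    @property
    def percent_atp(self) -> int:
        return _round_half_up(100.0 * self.proportion_atp)

    @property
    def percent_ats(self) -> int:
        return _round_half_up(100.0 * self.proportion_ats)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def aggregate_cohort(per_patient_counts: Iterable[Tuple[int, int]]) -> CohortSummary:
    """Aggregate per-patient (n_ATP, n_ATS) counts into cohort totals.

    Percentages are rounded half-up to integer percent.
    """
    rows = [(int(a), int(s)) for a, s in per_patient_counts]
    if not rows:
        raise ValueError("empty cohort")
    if any(a < 0 or s < 0 for a, s in rows):
        raise ValueError("counts must be non-negative")
    total_atp = sum(a for a, _ in rows)
    total_ats = sum(s for _, s in rows)
    if total_atp + total_ats == 0:
        raise ValueError("cohort has zero fractions")
    return CohortSummary(per_patient=rows, total_atp=total_atp, total_ats=total_ats)


# ---------------------------------------------------------------------------
# registration before/after comparison
# ---------------------------------------------------------------------------


@dataclass
class RegistrationComparison:
    """Mean Dice / Hausdorff before and after registration over cases."""

    dice_pre: float
    dice_post: float
    hd_pre_mm: float
    hd_post_mm: float
    per_structure: Dict[str, Dict[str, float]]


def compare_registration(model, cases: Sequence,
                         structures: Optional[Sequence[str]] = None,
                         fields: Optional[Sequence] = None
                         ) -> RegistrationComparison:
    """Apply a registration model to cases and score structure alignment.

    For every case and structure: pre = (moving mask vs fixed mask),
    post = (moving mask warped by the predicted field vs fixed mask).
    ``fields`` may carry precomputed displacement fields (one per case) to
    avoid re-running registration.
    """
    from .dlir import register, warp

    d_pre: Dict[str, List[float]] = {}
    d_post: Dict[str, List[float]] = {}
    h_pre: Dict[str, List[float]] = {}
    h_post: Dict[str, List[float]] = {}
    for idx, case in enumerate(cases):
        if fields is not None:
            field = fields[idx]
        else:
            field, _ = register(model, case.fixed, case.moving)
        names = structures if structures is not None else sorted(case.structures)
        for name in names:
            fixed_mask = case.structures[name].data > 0.5
            moving_mask = case.structures_moving[name]
            warped_mask = warp(moving_mask, field).data > 0.5
            sp = case.fixed.spacing
            d_pre.setdefault(name, []).append(dice(moving_mask.data, fixed_mask))
            d_post.setdefault(name, []).append(dice(warped_mask, fixed_mask))
            h_pre.setdefault(name, []).append(hausdorff(moving_mask.data, fixed_mask, sp))
            h_post.setdefault(name, []).append(hausdorff(warped_mask, fixed_mask, sp))
    per_structure = {
        name: {
            "dice_pre": float(np.mean(d_pre[name])),
            "dice_post": float(np.mean(d_post[name])),
            "hd_pre_mm": float(np.mean(h_pre[name])),
            "hd_post_mm": float(np.mean(h_post[name])),
        }
        for name in d_pre
    }
    return RegistrationComparison(
        dice_pre=float(np.mean([v for vs in d_pre.values() for v in vs])),
        dice_post=float(np.mean([v for vs in d_post.values() for v in vs])),
        hd_pre_mm=float(np.mean([v for vs in h_pre.values() for v in vs])),
        hd_post_mm=float(np.mean([v for vs in h_post.values() for v in vs])),
        per_structure=per_structure,
    )
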