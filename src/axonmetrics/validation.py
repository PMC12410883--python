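"""Segmentation-validation protocol: overlap metrics, instance matching,
and paired-measurement agreement.

Per-pixel quality is summarized by IoU (Jaccard), Dice and the 95th
percentile of symmetric boundary-to-boundary distances (HD95, in µm).
Instances are matched one-to-one between prediction and ground truth when
their areas overlap by more than a threshold fraction (40% by default, on
both the ground-truth and the prediction side); unmatched predictions are
false positives and unmatched ground-truth fibers false negatives.
Agreement of paired per-fiber measurements is assessed Bland-Altman
style: deltas (validation minus prediction), their mean, the ±1.96 sd
limits of agreement, the mean absolute error, and size-stratified deltas
keyed by the ground-truth axon diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import InstanceMaps

__all__ = [
    "PixelMetrics",
    "MatchResult",
    "AgreementReport",
    "pixel_metrics",
    "match_instances",
    "paired_agreement",
]


@dataclass(frozen=True)
class PixelMetrics:
    """Overlap scores of one predicted/ground-truth mask pair."""

    iou: float
    dice: float
    hausdorff95_um: float


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask, border_value=0)


def pixel_metrics(
    pred_mask: np.ndarray, gt_mask: np.ndarray, pixel_size_nm: float
) -> PixelMetrics:
    """IoU, Dice and the 95th-percentile Hausdorff distance (µm).

    Two empty masks agree perfectly by convention (IoU = Dice = 1,
    HD95 = 0); one empty mask scores 0/0 with an infinite HD95.
    """
    a = np.asarray(pred_mask, bool)
    b = np.asarray(gt_mask, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return PixelMetrics(iou=1.0, dice=1.0, hausdorff95_um=0.0)
    if na == 0 or nb == 0:
        return PixelMetrics(iou=0.0, dice=0.0, hausdorff95_um=np.inf)
    inter = int((a & b).sum())
    union = na + nb - inter
    iou = inter / union
    dice = 2 * inter / (na + nb)

    ba, bb = _boundary(a), _boundary(b)
    # nearest-boundary distances via the EDT of each boundary's complement
    d_to_b = ndi.distance_transform_edt(~bb)[ba]
    d_to_a = ndi.distance_transform_edt(~ba)[bb]
    all_d = np.concatenate([d_to_b, d_to_a])
    hd95 = float(np.percentile(all_d, 95)) * pixel_size_nm / 1000.0
    return PixelMetrics(iou=iou, dice=dice, hausdorff95_um=hd95)


@dataclass
class MatchResult:
    """One-to-one instance correspondence between prediction and truth."""

    matches: list[tuple[int, int, float]]  # (gt_id, pred_id, overlap fraction)
    false_positives: list[int] = field(default_factory=list)  # unmatched pred ids
    false_negatives: list[int] = field(default_factory=list)  # unmatched gt ids

    @property
    def matched_gt(self) -> dict[int, int]:
        return {g: p for g, p, _ in self.matches}


def _instance_footprints(inst: InstanceMaps) -> np.ndarray:
    """Per-pixel fiber id over the union of both compartments."""
    return np.where(inst.axon_labels > 0, inst.axon_labels, inst.myelin_labels).astype(
        np.int64
    )


def match_instances(
    pred: InstanceMaps,
    gt: InstanceMaps,
    threshold: float = 0.40,
    two_sided: bool = True,
) -> MatchResult:
    """Greedy one-to-one matching of instances by overlap fraction.

    A candidate pair must overlap by more than ``threshold`` of the
    ground-truth area and (if ``two_sided``) of the prediction area.
    Candidates are matched in order of decreasing overlap; each id is used
    at most once. Unmatched predictions become false positives, unmatched
    ground-truth fibers false negatives.
    """
    p = _instance_footprints(pred)
    g = _instance_footprints(gt)
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth must share a shape")

    p_ids, p_areas = np.unique(p[p > 0], return_counts=True)
    g_ids, g_areas = np.unique(g[g > 0], return_counts=True)
    p_area = dict(zip(p_ids.tolist(), p_areas.tolist()))
    g_area = dict(zip(g_ids.tolist(), g_areas.tolist()))

    both = (p > 0) & (g > 0)
    pairs, counts = np.unique(
        np.stack([g[both], p[both]]), axis=1, return_counts=True
    )
    candidates = []
    for (gid, pid), inter in zip(pairs.T.tolist(), counts.tolist()):
        frac_gt = inter / g_area[gid]
        frac_pred = inter / p_area[pid]
        ok = frac_gt > threshold and (frac_pred > threshold or not two_sided)
        if ok:
            candidates.append((min(frac_gt, frac_pred), gid, pid))
    candidates.sort(reverse=True)

    used_g: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for frac, gid, pid in candidates:
        if gid in used_g or pid in used_p:
            continue
        used_g.add(gid)
        used_p.add(pid)
        matches.append((gid, pid, frac))
    fps = [int(i) for i in p_ids if i not in used_p]
    fns = [int(i) for i in g_ids if i not in used_g]
    return MatchResult(matches=matches, false_positives=fps, false_negatives=fns)


@dataclass
class AgreementReport:
    """Bland-Altman-style agreement of one paired measure."""

    measure: str
    deltas: np.ndarray  # validation - prediction, one per matched pair
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    mae: float
    by_size: pd.DataFrame  # gt axon diameter vs delta, for size-stratified error

    def summary(self) -> dict:
        return {
            "measure": self.measure,
            "n": int(len(self.deltas)),
            "mean_difference": self.mean_difference,
            "loa": [self.loa_low, self.loa_high],
            "mae": self.mae,
        }


def paired_agreement(
    pred_values: np.ndarray,
    gt_values: np.ndarray,
    measure: str = "",
    gt_axon_diameter_um: np.ndarray | None = None,
) -> AgreementReport:
    """Agreement between matched predicted and ground-truth measurements.

    Deltas are validation (ground truth) minus prediction; limits of
    agreement are mean ± 1.96 sd on the raw scale.
    """
    pred_values = np.asarray(pred_values, dtype=float)
    gt_values = np.asarray(gt_values, dtype=float)
    if pred_values.size == 0:
        raise ValueError("paired agreement needs a non-empty match set")
    if pred_values.shape != gt_values.shape:
        raise ValueError("paired arrays must have equal length")
    deltas = gt_values - pred_values
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
    if gt_axon_diameter_um is None:
        gt_axon_diameter_um = np.full_like(deltas, np.nan)
    by_size = pd.DataFrame(
        {"gt_axon_diameter_um": gt_axon_diameter_um, "delta": deltas}
    ).sort_values("gt_axon_diameter_um", ignore_index=True)
    return AgreementReport(
        measure=measure,
        deltas=deltas,
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        mae=float(np.abs(deltas).mean()),
        by_size=by_size,
    )
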