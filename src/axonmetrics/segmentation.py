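"""Instance segmentation of axon/myelin semantic maps.

The post-processing chain converts per-pixel class scores into per-fiber
labels: the semantic map is thresholded (per-pixel argmax) into binary
axon and myelin masks and cleaned with small morphological operations;
the two masks are then joined, a Euclidean distance transform of the
union is computed, and a watershed on the inverted transform — seeded at
the transform's local maxima — partitions the union into one basin per
fiber, separating touching ("kissing") sheaths. Each basin is finally
split back into its axon and myelin compartments using the binary masks,
and implausible fibers (g-ratio above 1, extreme sizes, border contact,
missing sheaths) are filtered out with machine-readable reasons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist
from skimage.feature import peak_local_max
from skimage.morphology import closing, disk, remove_small_objects
from skimage.segmentation import watershed

from .containers import AXON, MYELIN, InstanceMaps, SemanticMap
from .morphometry import FiberRecord

__all__ = [
    "FilterRule",
    "preprocess_contrast",
    "threshold_semantic",
    "separate_instances",
    "segment",
    "filter_instances",
]


def preprocess_contrast(
    raw_image: np.ndarray, clip_limit: float = 0.01, tile_size: int = 64
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    Output is rescaled back to the input value range. Intended for raw
    electron micrographs ahead of semantic prediction; phantom semantic
    maps bypass this stage.
    """
    img = np.asarray(raw_image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {img.shape}")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img.copy()
    norm = (img - lo) / (hi - lo)
    eq = equalize_adapthist(norm, kernel_size=tile_size, clip_limit=clip_limit)
    return eq * (hi - lo) + lo


def threshold_semantic(
    smap: SemanticMap,
    min_object_px: int = 10,
    selem_radius: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold a semantic map into cleaned binary axon and myelin masks.

    Per-pixel argmax assigns each pixel to its highest-scoring class; the
    myelin mask is then closed and hole-filled (holes not claimed by an
    axon become sheath), the axon mask cleaned by opening-by-
    reconstruction, and objects below ``min_object_px`` removed. The two
    masks are disjoint.
    """
    classes = smap.class_map()
    axon = classes == AXON
    myelin = classes == MYELIN

    selem = disk(selem_radius)
    # opening-by-reconstruction: drops sub-element debris but leaves the
    # shape of surviving components untouched (clean one-hot maps pass
    # through identically)
    axon = ndi.binary_propagation(ndi.binary_erosion(axon, selem), mask=axon)
    myelin = closing(myelin, selem)
    myelin = ndi.binary_fill_holes(myelin) & ~axon

    if min_object_px > 1:
        axon = remove_small_objects(axon, max_size=min_object_px - 1)
        myelin = remove_small_objects(myelin, max_size=min_object_px - 1)
    return axon, myelin


def separate_instances(
    axon_mask: np.ndarray,
    myelin_mask: np.ndarray,
    peak_min_distance: int = 10,
    pixel_size_nm: float | None = None,
    smoothing_sigma: float = 1.0,
) -> InstanceMaps:
    """Partition the mask union into fiber instances by seeded watershed.

    Seeds are the local maxima of the (lightly smoothed) Euclidean
    distance transform of the joined axon+myelin mask, at least
    ``peak_min_distance`` px apart within each connected component; the
    watershed floods the inverted transform from these seeds. Each basin
    is split back into its axon and myelin compartments with the input
    masks; ids are dense from 1.
    """
    if axon_mask.shape != myelin_mask.shape:
        raise ValueError("axon and myelin masks must share a shape")
    if peak_min_distance < 1:
        raise ValueError("peak_min_distance must be >= 1 px")
    union = np.asarray(axon_mask, bool) | np.asarray(myelin_mask, bool)
    px = pixel_size_nm if pixel_size_nm is not None else 17.28
    if not union.any():
        z = np.zeros(union.shape, dtype=np.uint16)
        return InstanceMaps(z, z.copy(), px)

    edt = ndi.distance_transform_edt(union)
    if smoothing_sigma > 0:
        # suppresses plateau splitting of elongated (obliquely cut) fibers
        edt = ndi.gaussian_filter(edt, smoothing_sigma)
    comp_labels, _ = ndi.label(union)
    coords = peak_local_max(
        edt,
        min_distance=peak_min_distance,
        labels=comp_labels,
        exclude_border=False,
    )
    markers = np.zeros(union.shape, dtype=np.int32)
    markers[tuple(coords.T)] = 1 + np.arange(len(coords))
    basins = watershed(-edt, markers, mask=union)

    # dense relabeling from 1 in order of first appearance of marker ids
    ids = np.unique(basins)
    ids = ids[ids > 0]
    remap = np.zeros(int(ids.max()) + 1, dtype=np.int64)
    remap[ids] = 1 + np.arange(len(ids))
    basins = remap[basins]

    dtype = np.uint16 if len(ids) <= 65535 else np.int32
    axon_labels = np.where(np.asarray(axon_mask, bool), basins, 0).astype(dtype)
    myelin_labels = np.where(np.asarray(myelin_mask, bool), basins, 0).astype(dtype)
    return InstanceMaps(axon_labels, myelin_labels, px)


def segment(
    smap: SemanticMap,
    min_object_px: int = 10,
    peak_min_distance: int = 10,
) -> InstanceMaps:
    """Threshold then separate: the full semantic-to-instance chain."""
    axon, myelin = threshold_semantic(smap, min_object_px=min_object_px)
    return separate_instances(
        axon, myelin, peak_min_distance=peak_min_distance,
        pixel_size_nm=smap.pixel_size_nm,
    )


@dataclass(frozen=True)
class FilterRule:
    """Plausibility bounds for measured fibers; lengths in µm.

    Defaults span the physiological range of human white-matter fibers
    with wide margins; they are meant to catch segmentation failures, not
    to trim the population. ``drop_border_fibers`` removes fibers touching
    the image edge, whose ellipses are truncated and unmeasurable.
    """

    min_axon_diameter_um: float = 0.1
    max_axon_diameter_um: float = 15.0
    min_outer_diameter_um: float = 0.2
    max_outer_diameter_um: float = 20.0
    min_g_ratio: float = 0.0
    max_g_ratio: float = 1.0
    drop_border_fibers: bool = True

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_axon_diameter_um, self.max_axon_diameter_um, "axon diameter"),
            (self.min_outer_diameter_um, self.max_outer_diameter_um, "outer diameter"),
            (self.min_g_ratio, self.max_g_ratio, "g-ratio"),
        ):
            if lo >= hi:
                raise ValueError(f"{name} bounds must satisfy min < max")


def filter_instances(
    records: list[FiberRecord], rule: FilterRule | None = None
) -> tuple[list[FiberRecord], list[tuple[FiberRecord, str]]]:
    """Split records into plausible fibers and rejects with reason codes.

    Reason codes: ``no_axon``, ``no_myelin``, ``degenerate_region``,
    ``touches_border``, ``axon_diameter_out_of_range``,
    ``outer_diameter_out_of_range``, ``g_ratio_out_of_range``. The first
    failed check (in that order) names the rejection.
    """
    rule = rule or FilterRule()
    kept: list[FiberRecord] = []
    rejected: list[tuple[FiberRecord, str]] = []
    for rec in records:
        reason = _rejection_reason(rec, rule)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def _rejection_reason(rec: FiberRecord, rule: FilterRule) -> str | None:
    if "no_axon" in rec.qc_flags:
        return "no_axon"
    if "no_myelin" in rec.qc_flags:
        return "no_myelin"
    if "degenerate_axon" in rec.qc_flags or "degenerate_outer" in rec.qc_flags:
        return "degenerate_region"
    if rule.drop_border_fibers and "touches_border" in rec.qc_flags:
        return "touches_border"
    d = rec.axon_minor_um
    if not rule.min_axon_diameter_um <= d <= rule.max_axon_diameter_um:
        return "axon_diameter_out_of_range"
    D = rec.outer_minor_um
    if not rule.min_outer_diameter_um <= D <= rule.max_outer_diameter_um:
        return "outer_diameter_out_of_range"
    if not rule.min_g_ratio < rec.g_ratio <= rule.max_g_ratio:
        return "g_ratio_out_of_range"
    return None
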