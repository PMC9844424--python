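"""Semi-automated reference-standard labeling for fat-only Dixon slices.

The reference pipeline mirrors how expert readers label these images:
bright fat pixels are thresholded at a fraction (default 50%) of the
maximum signal intensity over the trunk region, spurious fat islands
(spinal canal, neural foramina) are excluded, and the remaining fat is
split into subcutaneous (SAT) and visceral (VAT) compartments by the
nested outer/inner abdominal-wall regions. Manual correction is exposed
as a scripted edit API rather than a GUI.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Contour, DixonSlice, FatMasks, RegionPair

__all__ = [
    "threshold_fat",
    "remove_islands",
    "split_fat_by_region",
    "reference_pipeline",
    "apply_mask_edit",
    "apply_contour_edit",
]


def threshold_fat(
    slc: DixonSlice,
    support: np.ndarray,
    fraction: float = 0.5,
    robust_percentile: Optional[float] = None,
) -> np.ndarray:
    """Classify fat pixels as those at or above ``fraction`` of the peak signal.

    The reference maximum is taken over ``support`` (normally the outer
    trunk region) rather than the whole image, so out-of-body artifacts
    cannot inflate it. The comparison is inclusive: intensity exactly at
    the threshold counts as fat. With ``robust_percentile`` set (e.g.
    99.5), that percentile of the support intensities replaces the strict
    maximum, guarding against isolated hot pixels.
    """
    support = np.asarray(support).astype(bool)
    if support.shape != slc.shape:
        raise ValueError("support mask shape must match the image")
    if not support.any():
        raise ValueError("support mask is empty")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    vals = slc.intensities[support]
    peak = float(np.percentile(vals, robust_percentile)) if robust_percentile \
        else float(vals.max())
    thr = fraction * peak
    return support & (slc.intensities >= thr)


def remove_islands(
    fat_mask: np.ndarray,
    exclusion_roi: Optional[np.ndarray] = None,
    min_area: int = 0,
) -> np.ndarray:
    """Drop fat pixels inside an exclusion ROI and small connected components.

    ``exclusion_roi`` models the reader outlining spinal-canal/foraminal
    fat to discard; ``min_area`` (pixels, default 0 = keep all) optionally
    removes speckle components below that size. 8-connectivity.
    """
    fat = np.asarray(fat_mask).astype(bool).copy()
    if exclusion_roi is not None:
        roi = np.asarray(exclusion_roi).astype(bool)
        if roi.shape != fat.shape:
            raise ValueError("exclusion_roi shape must match fat mask")
        fat &= ~roi
    if min_area > 0 and fat.any():
        lab, n = ndimage.label(fat, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_area
        keep[0] = False
        fat = keep[lab]
    return fat


def split_fat_by_region(fat_mask: np.ndarray, regions: RegionPair) -> FatMasks:
    """Split fat into SAT/VAT by the nested regions.

    VAT is fat inside the inner region; SAT is fat in the abdominal-wall
    ring (outer minus inner); fat outside the outer region is discarded.
    Pixel count is conserved: |SAT| + |VAT| = |fat ∩ outer|.
    """
    fat = np.asarray(fat_mask).astype(bool)
    if fat.shape != regions.outer_mask.shape:
        raise ValueError("fat mask shape must match the regions")
    vat = fat & regions.inner_mask
    sat = fat & regions.ring_mask
    return FatMasks(sat_mask=sat, vat_mask=vat)


def reference_pipeline(
    slc: DixonSlice,
    regions: RegionPair,
    fraction: float = 0.5,
    exclusion_roi: Optional[np.ndarray] = None,
    min_area: int = 0,
    robust_percentile: Optional[float] = None,
) -> FatMasks:
    """Full reference labeling: threshold, island exclusion, region split."""
    fat = threshold_fat(slc, regions.outer_mask, fraction=fraction,
                        robust_percentile=robust_percentile)
    fat = remove_islands(fat, exclusion_roi=exclusion_roi, min_area=min_area)
    return split_fat_by_region(fat, regions)


# ---------------------------------------------------------------------------
# scripted manual corrections
# ---------------------------------------------------------------------------

def apply_mask_edit(masks: FatMasks, target: str, action: str,
                    pixels: np.ndarray) -> FatMasks:
    """Add or remove an explicit pixel set on one of the fat masks.

    ``pixels`` is an ``(n, 2)`` integer array of (row, col) coordinates;
    ``target`` is ``"sat"`` or ``"vat"``; ``action`` is ``"add"`` or
    ``"remove"``. Adding to one mask clears those pixels from the other so
    the masks stay disjoint. Adding then removing the same set restores
    the original mask.
    """
    if target not in ("sat", "vat"):
        raise ValueError("target must be 'sat' or 'vat'")
    if action not in ("add", "remove"):
        raise ValueError("action must be 'add' or 'remove'")
    pix = np.atleast_2d(np.asarray(pixels, dtype=int))
    sat = masks.sat_mask.copy()
    vat = masks.vat_mask.copy()
    h, w = sat.shape
    if np.any(pix < 0) or np.any(pix[:, 0] >= h) or np.any(pix[:, 1] >= w):
        raise ValueError("edit addresses coordinates outside the image")
    rows, cols = pix[:, 0], pix[:, 1]
    tgt, other = (sat, vat) if target == "sat" else (vat, sat)
    if action == "add":
        tgt[rows, cols] = True
        other[rows, cols] = False
    else:
        tgt[rows, cols] = False
    return FatMasks(sat_mask=sat, vat_mask=vat)


def apply_contour_edit(regions: RegionPair, which: str,
                       vertex_index: int, displacement: tuple[float, float],
                       contours: dict[str, Contour],
                       image_shape: tuple[int, int]) -> tuple[RegionPair, dict[str, Contour]]:
    """Displace one vertex of the outer or inner contour and re-rasterize.

    The edit is rejected (ValueError) if the resulting regions violate the
    nesting invariant inner ⊆ outer or the contour self-intersects.
    """
    from . import image_io

    if which not in ("outer", "inner"):
        raise ValueError("which must be 'outer' or 'inner'")
    new_contours = dict(contours)
    c = contours[which]
    verts = c.vertices.copy()
    if not (0 <= vertex_index < len(verts)):
        raise ValueError("vertex_index out of range")
    verts[vertex_index] += np.asarray(displacement, dtype=float)
    new_contours[which] = Contour(verts, role=c.role)
    outer = image_io.contour_to_region(new_contours["outer"], image_shape)
    inner = image_io.contour_to_region(new_contours["inner"], image_shape)
    if np.any(inner & ~outer):
        raise ValueError("edit rejected: inner contour would leave the outer region")
    return RegionPair(outer, inner), new_contours
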