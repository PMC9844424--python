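"""Fuse the region model and fat model outputs into four-class labels.

The region network proposes outer/inner abdominal regions; the fat
network proposes SAT/VAT pixels. Fusion first repairs the regions
(largest connected component, hole filling, strict nesting), then gates
the fat pixels geometrically: fat inside the inner region is VAT, fat in
the wall ring is SAT, fat outside the trunk is discarded. The geometric
gate is the only combination rule that guarantees the anatomical
invariants (VAT confined to the abdominal cavity, SAT to the wall ring);
trusting the fat model's own SAT/VAT call, with the regions used only as
a trunk mask, is available via ``region_override=False``. A
threshold-based fallback mode re-labels fat with the reference 50%-of-max
rule inside the CNN regions, for interactive correction of suboptimal
CNN fat predictions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .core import DixonSlice, FatMasks, FourClassLabelMap, LABEL_CODES, RegionPair
from . import reference

__all__ = ["enforce_nesting", "fuse_labels", "run_inference"]


def _largest_component(mask: np.ndarray, name: str) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError(f"{name} region prediction is empty")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def enforce_nesting(outer_pred: np.ndarray, inner_pred: np.ndarray) -> RegionPair:
    """Repair raw region predictions into a strictly nested pair.

    Keeps the largest connected component of each mask, fills interior
    holes, then clips the inner region to the outer region eroded by one
    pixel so the nesting ``inner ⊂ outer`` is strict. Already-clean nested
    masks pass through unchanged.
    """
    outer = np.asarray(outer_pred).astype(bool)
    inner = np.asarray(inner_pred).astype(bool)
    if outer.shape != inner.shape:
        raise ValueError("outer and inner predictions must share a shape")
    outer = ndimage.binary_fill_holes(_largest_component(outer, "outer"))
    inner = ndimage.binary_fill_holes(_largest_component(inner, "inner"))
    eroded = ndimage.binary_erosion(outer, structure=np.ones((3, 3), dtype=bool))
    inner &= eroded
    if not inner.any():
        raise ValueError("inner region prediction vanished after nesting repair")
    return RegionPair(outer_mask=outer, inner_mask=inner)


def fuse_labels(
    regions: RegionPair,
    fat_pred: FatMasks,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    region_override: bool = True,
) -> FourClassLabelMap:
    """Combine regions and fat predictions into the four-class label map.

    With ``region_override`` (default) any predicted fat pixel — whether
    the fat model called it SAT or VAT — is relabeled by its location:
    VAT inside the inner region, SAT in the wall ring, background outside
    the trunk. Fat pixel count inside the outer region is conserved:
    ``|SAT| + |VAT| = |fat ∩ outer|``. With ``region_override=False`` the
    fat model's own class call is kept and the regions act only as masks
    (SAT restricted to the ring, VAT to the inner region).
    """
    fat_any = fat_pred.sat_mask | fat_pred.vat_mask
    if fat_any.shape != regions.outer_mask.shape:
        raise ValueError("fat prediction shape must match the regions")
    labels = np.zeros(fat_any.shape, dtype=np.int64)
    if region_override:
        labels[fat_any & regions.ring_mask] = LABEL_CODES["sat"]
        labels[fat_any & regions.inner_mask] = LABEL_CODES["vat"]
    else:
        labels[fat_pred.sat_mask & regions.ring_mask] = LABEL_CODES["sat"]
        labels[fat_pred.vat_mask & regions.inner_mask] = LABEL_CODES["vat"]
    out = FourClassLabelMap(labels=labels, regions=regions,
                            pixel_spacing_mm=pixel_spacing_mm)
    out.validate()
    return out


def run_inference(
    slc: DixonSlice,
    region_model,
    fat_model=None,
    mode: str = "cnn",
    regions: Optional[RegionPair] = None,
    fraction: float = 0.5,
    exclusion_roi: Optional[np.ndarray] = None,
    region_override: bool = True,
) -> FourClassLabelMap:
    """End-to-end single-slice inference.

    ``mode="cnn"``: region model → nesting repair, fat model → SAT/VAT,
    then :func:`fuse_labels`. ``mode="threshold_fallback"``: the CNN
    regions (or explicitly supplied ``regions``) combined with the
    reference 50%-of-max threshold labeling instead of the fat network.
    Both modes emit the same ``FourClassLabelMap`` schema.
    """
    from .nn.training import predict

    if mode not in ("cnn", "threshold_fallback"):
        raise ValueError(f"unknown mode {mode!r}")
    if regions is None:
        if region_model is None:
            raise ValueError("need a region model or explicit regions")
        _, region_labels = predict(region_model, slc)
        regions = enforce_nesting(region_labels > 0, region_labels == 2)
    if mode == "cnn":
        if fat_model is None:
            raise ValueError("cnn mode requires a fat model")
        _, fat_labels = predict(fat_model, slc)
        fat_pred = FatMasks(sat_mask=fat_labels == 1, vat_mask=fat_labels == 2)
    else:
        fat_pred = reference.reference_pipeline(
            slc, regions, fraction=fraction, exclusion_roi=exclusion_roi
        )
    return fuse_labels(regions, fat_pred, pixel_spacing_mm=slc.pixel_spacing_mm,
                       region_override=region_override)
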