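"""Core domain containers for single-slice Dixon fat quantification.

Conventions used throughout the package:

* arrays are 2D, indexed ``(row, col)``, 0-based;
* masks are boolean pixel sets;
* contour vertices live in continuous pixel coordinates with pixel centers
  at integer positions;
* label maps use the integer codes in :data:`LABEL_CODES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LABEL_CODES",
    "DixonSlice",
    "Contour",
    "RegionPair",
    "FatMasks",
    "FourClassLabelMap",
]

#: Integer codes of the fused four-class output label map.
LABEL_CODES = {"background": 0, "sat": 1, "vat": 2}


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


@dataclass
class DixonSlice:
    """One axial fat-only Dixon slice with acquisition metadata.

    Parameters
    ----------
    intensities
        2D non-negative array; adipose tissue appears bright on the
        fat-only image, other soft tissue dark.
    pixel_spacing_mm
        In-plane spacing ``(row, col)`` in millimetres.
    subject_id, visit, level
        Cohort metadata; ``level`` is the intervertebral disc level of the
        slice ("L23" or "L45").
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    subject_id: str = ""
    visit: int = 0
    level: str = "L23"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")
        self.intensities = arr
        self.pixel_spacing_mm = (float(sr), float(sc))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def with_intensities(self, arr: np.ndarray) -> "DixonSlice":
        """Copy of this slice with new pixel data, metadata preserved."""
        return replace(self, intensities=np.asarray(arr, dtype=np.float64))


@dataclass
class Contour:
    """A closed planar contour in pixel coordinates.

    ``vertices`` is an ordered ``(n, 2)`` array of ``(row, col)`` points;
    the polygon is implicitly closed (last vertex connects to the first).
    ``role`` tags the contour as the outer body surface or the inner
    abdominal-wall boundary.
    """

    vertices: np.ndarray
    role: str = "outer"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(v) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        if self.role not in ("outer", "inner"):
            raise ValueError(f"role must be 'outer' or 'inner', got {self.role!r}")
        self.vertices = v

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise order in (row, col)."""
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))

    def is_simple(self) -> bool:
        """True if the closed polygon does not self-intersect."""
        from shapely.geometry import LinearRing

        try:
            return LinearRing(self.vertices).is_valid
        except Exception:
            return False


@dataclass
class RegionPair:
    """Nested outer/inner abdominal regions.

    ``outer_mask`` covers the whole trunk cross-section out to the skin;
    ``inner_mask`` the abdominal cavity inside the wall. The set difference
    ``outer \\ inner`` is the subcutaneous fat compartment; the inner region
    is the visceral compartment.
    """

    outer_mask: np.ndarray
    inner_mask: np.ndarray

    def __post_init__(self) -> None:
        self.outer_mask = _as_bool(self.outer_mask, "outer_mask")
        self.inner_mask = _as_bool(self.inner_mask, "inner_mask")
        if self.outer_mask.shape != self.inner_mask.shape:
            raise ValueError("outer and inner masks must share a shape")
        if not self.outer_mask.any():
            raise ValueError("outer_mask is empty")
        if not self.inner_mask.any():
            raise ValueError("inner_mask is empty")
        if np.any(self.inner_mask & ~self.outer_mask):
            raise ValueError("inner region must be contained in the outer region")

    @property
    def ring_mask(self) -> np.ndarray:
        """The abdominal-wall ring ``outer \\ inner`` (SAT compartment)."""
        return self.outer_mask & ~self.inner_mask


@dataclass
class FatMasks:
    """Mutually exclusive SAT and VAT pixel masks."""

    sat_mask: np.ndarray
    vat_mask: np.ndarray

    def __post_init__(self) -> None:
        self.sat_mask = _as_bool(self.sat_mask, "sat_mask")
        self.vat_mask = _as_bool(self.vat_mask, "vat_mask")
        if self.sat_mask.shape != self.vat_mask.shape:
            raise ValueError("sat and vat masks must share a shape")
        if np.any(self.sat_mask & self.vat_mask):
            raise ValueError("sat and vat masks must be disjoint")


@dataclass
class FourClassLabelMap:
    """Fused output: integer labels plus the companion region pair.

    ``labels`` uses :data:`LABEL_CODES` (0 background, 1 SAT, 2 VAT); the
    outer/inner context that makes the four-class semantics
    (outer region, inner region, SAT, VAT) explicit travels alongside in
    ``regions``.
    """

    labels: np.ndarray
    regions: RegionPair
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2D")
        if lab.shape != self.regions.outer_mask.shape:
            raise ValueError("labels and region masks must share a shape")
        bad = set(np.unique(lab)) - set(LABEL_CODES.values())
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")
        self.labels = lab.astype(np.int64, copy=False)

    @property
    def sat_mask(self) -> np.ndarray:
        return self.labels == LABEL_CODES["sat"]

    @property
    def vat_mask(self) -> np.ndarray:
        return self.labels == LABEL_CODES["vat"]

    def validate(self) -> None:
        """Raise if the anatomical nesting invariants are violated."""
        ring = self.regions.ring_mask
        if np.any(self.sat_mask & ~ring):
            raise ValueError("SAT pixels must lie in the abdominal-wall ring")
        if np.any(self.vat_mask & ~self.regions.inner_mask):
            raise ValueError("VAT pixels must lie inside the inner region")

    def areas(self) -> dict[str, float]:
        """Pixel counts and cm^2 areas per class (see also stats.area_summary)."""
        sr, sc = self.pixel_spacing_mm
        px_cm2 = sr * sc / 100.0
        out = {}
        for name, mask in (
            ("outer", self.regions.outer_mask),
            ("inner", self.regions.inner_mask),
            ("sat", self.sat_mask),
            ("vat", self.vat_mask),
        ):
            n = int(mask.sum())
            out[f"{name}_pixels"] = n
            out[f"{name}_cm2"] = n * px_cm2
        return out
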