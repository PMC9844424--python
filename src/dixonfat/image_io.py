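"""Image, label-map, and contour I/O plus geometric pre/post-processing.

Formats: NIfTI (.nii/.nii.gz) for intensity images and integer label maps,
single-frame DICOM read, single-channel 8/16-bit PNG, and JSON contours
``{"role": "outer"|"inner", "vertices": [[r, c], ...]}``.

Also provides min-max intensity normalization to [0, 1], symmetric
zero-padding (or resampling) to the network input size with an exact
inverse, the two-point Dixon fat/water decomposition, and conversions
between binary regions and sub-pixel boundary contours.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import Contour, DixonSlice

__all__ = [
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "read_contours",
    "write_contours",
    "normalize_intensity",
    "harmonize_size",
    "unharmonize_size",
    "pad_to",
    "crop_to",
    "dixon_decompose",
    "dixon_recompose",
    "region_to_contour",
    "contour_to_region",
    "mask_from_contours",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> DixonSlice:
    """Read a 2D intensity image (NIfTI, DICOM, or single-channel PNG)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ValueError(f"expected a single 2D slice in {path}, got shape {arr.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]) or 1.0, float(zooms[1]) or 1.0)
        return DixonSlice(arr, pixel_spacing_mm=spacing)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValueError("only single-frame 2D DICOM is supported")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        return DixonSlice(np.clip(arr, 0, None),
                          pixel_spacing_mm=(float(spacing[0]), float(spacing[1])))
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        if arr.ndim != 2:
            raise ValueError(
                "PNG intensity images must be single-channel grayscale; "
                f"got shape {arr.shape}. Convert to 8/16-bit grayscale first."
            )
        return DixonSlice(arr.astype(np.float64))
    raise ValueError(f"unsupported image format: {path.name}")


def write_image(path: str | Path, slc: DixonSlice) -> None:
    """Write an intensity image as NIfTI (spacing preserved) or 16-bit PNG."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([slc.pixel_spacing_mm[0], slc.pixel_spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(slc.intensities.astype(np.float32), affine)
        img.header.set_zooms((slc.pixel_spacing_mm[0], slc.pixel_spacing_mm[1]))
        nib.save(img, str(path))
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = slc.intensities
        peak = arr.max() if arr.max() > 0 else 1.0
        iio.imwrite(str(path), np.round(arr / peak * 65535).astype(np.uint16))
        return
    raise ValueError(f"unsupported image format: {path.name}")


def read_labelmap(path: str | Path, classes: Optional[Sequence[int]] = None) -> np.ndarray:
    """Read an integer label map; optionally validate against a class set."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        arr = np.squeeze(np.asarray(nib.load(str(path)).dataobj))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        if arr.ndim != 2:
            raise ValueError("label PNGs must be single-channel")
    else:
        raise ValueError(f"unsupported label format: {path.name}")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path} does not contain integer labels")
    lab = np.round(arr).astype(np.int64)
    if classes is not None:
        bad = set(np.unique(lab)) - set(int(c) for c in classes)
        if bad:
            raise ValueError(f"label values outside declared class set: {sorted(bad)}")
    return lab


def write_labelmap(path: str | Path, labels: np.ndarray,
                   pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)) -> None:
    path = Path(path)
    labels = np.asarray(labels)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if labels.min() < 0 or labels.max() > 255:
            raise ValueError("PNG label maps support 0..255 only")
        iio.imwrite(str(path), labels.astype(np.uint8))
        return
    raise ValueError(f"unsupported label format: {path.name}")


def read_contours(path: str | Path) -> list[Contour]:
    """Read contours from JSON (a single object or a list of objects)."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [Contour(np.asarray(c["vertices"], dtype=float), role=c["role"]) for c in payload]


def write_contours(path: str | Path, contours: Sequence[Contour] | Contour) -> None:
    if isinstance(contours, Contour):
        contours = [contours]
    payload = [
        {"role": c.role, "vertices": np.asarray(c.vertices, dtype=float).tolist()}
        for c in contours
    ]
    with open(path, "w") as fh:
        json.dump(payload if len(payload) > 1 else payload[0], fh)


# ---------------------------------------------------------------------------
# intensity and size
# ---------------------------------------------------------------------------

def normalize_intensity(slc: DixonSlice) -> DixonSlice:
    """Affine rescale so the minimum maps to 0 and the maximum to 1."""
    arr = slc.intensities
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant image")
    return slc.with_intensities((arr - lo) / (hi - lo))


def _pad_amounts(n: int, target: int) -> tuple[int, int]:
    extra = target - n
    before = extra // 2
    return before, extra - before


def pad_to(arr: np.ndarray, target: int) -> np.ndarray:
    """Zero-pad a 2D array symmetrically about its center to target x target."""
    h, w = arr.shape
    if target < h or target < w:
        raise ValueError("pad target smaller than input; use resample mode")
    pr = _pad_amounts(h, target)
    pc = _pad_amounts(w, target)
    return np.pad(arr, (pr, pc))


def crop_to(arr: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
    """Exact inverse of :func:`pad_to` for the given original shape."""
    h, w = original_shape
    H, W = arr.shape
    pr0, _ = _pad_amounts(h, H)
    pc0, _ = _pad_amounts(w, W)
    return arr[pr0:pr0 + h, pc0:pc0 + w]


def harmonize_size(slc: DixonSlice, target: int, mode: str = "pad") -> DixonSlice:
    """Bring a slice to ``target x target`` pixels.

    ``mode="pad"`` (default) zero-pads symmetrically about the center and
    is exactly invertible with :func:`unharmonize_size`; ``mode="resample"``
    bilinearly resamples (masks should instead be resampled with
    nearest-neighbor semantics, order 0).
    """
    arr = slc.intensities
    if mode == "pad":
        return slc.with_intensities(pad_to(arr, target))
    if mode == "resample":
        from skimage.transform import resize

        out = resize(arr, (target, target), order=1, preserve_range=True,
                     anti_aliasing=False)
        return slc.with_intensities(out)
    raise ValueError(f"unknown mode {mode!r}")


def unharmonize_size(arr: np.ndarray, original_shape: tuple[int, int],
                     mode: str = "pad") -> np.ndarray:
    """Map an array (image, mask, or label map) back to the original frame."""
    if mode == "pad":
        return crop_to(np.asarray(arr), original_shape)
    if mode == "resample":
        from skimage.transform import resize

        return resize(np.asarray(arr, dtype=float), original_shape, order=0,
                      preserve_range=True, anti_aliasing=False).astype(np.asarray(arr).dtype)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Dixon decomposition
# ---------------------------------------------------------------------------

def dixon_decompose(in_phase: np.ndarray, out_phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-point Dixon water/fat separation.

    The in-phase echo measures water + fat, the out-of-phase echo
    water - fat; half-sum and half-difference recover the pure images:
    ``water = (IP + OP) / 2``, ``fat = (IP - OP) / 2``. The map is an
    exact linear bijection; :func:`dixon_recompose` inverts it to machine
    precision.
    """
    ip = np.asarray(in_phase, dtype=np.float64)
    op = np.asarray(out_phase, dtype=np.float64)
    if ip.shape != op.shape:
        raise ValueError(f"shape mismatch: {ip.shape} vs {op.shape}")
    water = (ip + op) / 2.0
    fat = (ip - op) / 2.0
    return water, fat


def dixon_recompose(water: np.ndarray, fat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`dixon_decompose`: returns (in_phase, out_phase)."""
    water = np.asarray(water, dtype=np.float64)
    fat = np.asarray(fat, dtype=np.float64)
    if water.shape != fat.shape:
        raise ValueError(f"shape mismatch: {water.shape} vs {fat.shape}")
    return water + fat, water - fat


# ---------------------------------------------------------------------------
# region <-> contour
# ---------------------------------------------------------------------------

def region_to_contour(mask: np.ndarray, role: str = "outer") -> list[Contour]:
    """Trace sub-pixel boundary contours of a binary mask at iso-level 0.5.

    One contour per connected foreground component, largest area first;
    interior holes are traced as separate contours with negative
    orientation (outer boundaries are positively oriented).
    """
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot trace contours of an empty mask")
    # pad so boundaries touching the frame still close
    padded = np.pad(mask.astype(float), 1)
    raw = measure.find_contours(padded, 0.5, positive_orientation="high")
    contours: list[tuple[float, Contour]] = []
    for verts in raw:
        verts = verts - 1.0  # undo padding offset
        if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            continue
        c = Contour(verts, role=role)
        contours.append((c.signed_area(), c))
    if not contours:
        raise ValueError("mask has no traceable boundary (too small)")
    # outer boundaries first, by descending enclosed area; holes after,
    # keeping their negative orientation
    contours.sort(key=lambda t: -abs(t[0]))
    return [c for _, c in contours]


def contour_to_region(contour: Contour, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one closed contour: pixel centers strictly inside the polygon.

    Uses an even-odd point-in-polygon test at integer pixel centers. The
    contour must not self-intersect.
    """
    if not contour.is_simple():
        raise ValueError("contour is self-intersecting")
    return _rasterize(contour.vertices, image_shape)


def _rasterize(vertices: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    from matplotlib.path import Path as MplPath

    h, w = image_shape
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    path = MplPath(vertices, closed=True)
    inside = path.contains_points(pts)
    return inside.reshape(h, w)


def mask_from_contours(contours: Sequence[Contour], image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize several contours with the even-odd rule (holes subtract)."""
    out = np.zeros(image_shape, dtype=bool)
    for c in contours:
        if not c.is_simple():
            raise ValueError("contour is self-intersecting")
        out ^= _rasterize(c.vertices, image_shape)
    return out
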