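"""Synthetic fat-only Dixon abdomen phantoms with exact ground truth.

The study data this package targets — axial fat-only Dixon slices of the
abdomen at the L2–L3 and L4–L5 disc levels — cannot be redistributed, so
every stage of the pipeline is exercised against a parametric phantom
instead. A phantom is a smoothly-perturbed ellipse (low-order angular
harmonics on the radius) with

* a bright subcutaneous fat ring between the outer body surface and the
  inner abdominal-wall boundary,
* scattered bright visceral fat blobs inside the inner boundary,
* darker non-fat tissue elsewhere inside the cavity,
* an optional bright fat island at the posterior midline standing in for
  spinal-canal fat that reference labeling must exclude,
* additive Gaussian noise and a smooth multiplicative bias field.

Ground-truth outer/inner regions and SAT/VAT masks are constructed
analytically, so downstream segmentation can be scored exactly. Cohorts of
subjects with repeated visits are generated with per-subject geometry that
drifts as a random walk across visits, mimicking longitudinal scans.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .core import DixonSlice, RegionPair

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "apply_degradation",
    "generate_cohort",
    "visit_counts_for_total",
    "truth_to_labelmap",
    "labelmap_to_truth",
    "TRUTH_CODES",
]

LEVELS = ("L23", "L45")

#: Integer codes used when a ground-truth object is stored as one label image.
TRUTH_CODES = {"air": 0, "sat": 1, "vat": 2, "tissue": 3, "spinal_island": 4}


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic slice.

    Lengths are in pixels, intensities in arbitrary units. The defaults
    describe a 384×384 slice at 1.1 mm spacing, matching a typical
    288–384 pixel abdominal Dixon reconstruction. ``fat_intensity`` must
    exceed twice ``tissue_intensity`` so that on a noiseless phantom the
    50%-of-maximum threshold rule separates fat from other tissue exactly.
    """

    image_size: int = 384
    center: Optional[tuple[float, float]] = None  # default: image center
    semi_axes: Optional[tuple[float, float]] = None  # (row, col); default from size
    boundary_wobble: float = 0.05  # fractional radial perturbation of the outline
    wall_thickness: Optional[float] = None  # mean SAT ring thickness, pixels
    wall_wobble: float = 0.25  # fractional thickness variation around the ring
    n_vat_blobs: int = 12
    vat_blob_radius_range: Optional[tuple[float, float]] = None
    fat_intensity: float = 600.0
    tissue_intensity: float = 150.0
    noise_sd: float = 10.0
    bias_amplitude: float = 0.15
    spinal_island: bool = True
    spinal_island_radius: Optional[float] = None
    spinal_island_offset: float = 0.72  # radial position, fraction of inner radius
    level: str = "L23"
    pixel_spacing_mm: float = 1.1

    def __post_init__(self) -> None:
        s = float(self.image_size)
        if self.center is None:
            self.center = (s / 2.0, s / 2.0)
        if self.semi_axes is None:
            self.semi_axes = (0.30 * s, 0.38 * s)
        if self.wall_thickness is None:
            # L4-L5 slices carry a thicker subcutaneous ring than L2-L3
            self.wall_thickness = (0.10 if self.level == "L45" else 0.08) * s
        if self.vat_blob_radius_range is None:
            self.vat_blob_radius_range = (0.015 * s, 0.045 * s)
        if self.spinal_island_radius is None:
            self.spinal_island_radius = 0.03 * s
        self.validate()

    @classmethod
    def for_level(cls, level: str, image_size: int = 384, **kw) -> "PhantomSpec":
        """Level-specific defaults: L4-L5 has a thicker wall and denser VAT."""
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
        kw.setdefault("n_vat_blobs", 14 if level == "L45" else 10)
        return cls(image_size=image_size, level=level, **kw)

    def validate(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if self.fat_intensity <= 2.0 * self.tissue_intensity:
            raise ValueError(
                "fat_intensity must exceed 2 x tissue_intensity so the "
                "50%-of-max threshold separates fat from tissue"
            )
        if self.tissue_intensity <= 0:
            raise ValueError("tissue_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if not (0.0 <= self.boundary_wobble < 0.3):
            raise ValueError("boundary_wobble must lie in [0, 0.3)")
        if not (0.0 <= self.wall_wobble < 1.0):
            raise ValueError("wall_wobble must lie in [0, 1)")
        lo, hi = self.vat_blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("vat_blob_radius_range must satisfy 0 < lo <= hi")
        if self.n_vat_blobs < 0:
            raise ValueError("n_vat_blobs must be >= 0")
        # geometry must fit in the frame with a safety margin
        cr, cc = self.center
        a, b = self.semi_axes
        margin = 2.0
        rmax_row = a * (1.0 + self.boundary_wobble)
        rmax_col = b * (1.0 + self.boundary_wobble)
        if (
            cr - rmax_row < margin
            or cr + rmax_row > self.image_size - margin
            or cc - rmax_col < margin
            or cc + rmax_col > self.image_size - margin
        ):
            raise ValueError("outer boundary does not fit inside the image frame")
        # inner boundary strictly inside the outer one at every angle
        wall_min = self.wall_thickness * (1.0 - self.wall_wobble)
        if wall_min < 1.0:
            raise ValueError("wall thickness must stay >= 1 pixel at every angle")
        r_out_min = min(a, b) * (1.0 - self.boundary_wobble)
        wall_max = self.wall_thickness * (1.0 + self.wall_wobble)
        if r_out_min - wall_max < 4.0:
            raise ValueError("inner region would collapse: wall too thick for ellipse")


@dataclass
class GroundTruth:
    """Exact pixel truth of one phantom."""

    outer_mask: np.ndarray
    inner_mask: np.ndarray
    sat_mask: np.ndarray
    vat_mask: np.ndarray
    spinal_island_mask: np.ndarray

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name)).astype(bool))

    def validate(self) -> None:
        """Raise unless the nesting/exclusivity invariants hold."""
        if np.any(self.inner_mask & ~self.outer_mask):
            raise ValueError("inner must be contained in outer")
        ring = self.outer_mask & ~self.inner_mask
        if np.any(self.sat_mask & ~ring):
            raise ValueError("sat must lie in outer \\ inner")
        if np.any(self.vat_mask & ~self.inner_mask):
            raise ValueError("vat must lie inside inner")
        if np.any(self.vat_mask & self.spinal_island_mask):
            raise ValueError("vat must exclude the spinal island")
        if np.any(self.sat_mask & self.vat_mask):
            raise ValueError("sat and vat must be disjoint")

    @property
    def regions(self) -> RegionPair:
        return RegionPair(self.outer_mask, self.inner_mask)

    @property
    def fat_mask(self) -> np.ndarray:
        """All designed bright-fat pixels, including the excluded island."""
        return self.sat_mask | self.vat_mask | self.spinal_island_mask


def _polar_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)  # theta=0 points toward increasing row (posterior)
    return rho, theta


def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[DixonSlice, GroundTruth]:
    """Render one phantom slice and its exact ground truth.

    Identical ``(spec, seed)`` pairs produce bit-identical outputs. Before
    noise and bias are applied, bright (``fat_intensity``) pixels are
    exactly the union of SAT, VAT, and the spinal island; everything else
    is at ``tissue_intensity`` (inside the cavity) or zero (air).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rho, theta = _polar_grids(spec)
    a, b = spec.semi_axes

    # outer outline: ellipse radius modulated by low-order harmonics
    orders = (2, 3, 4)
    amps = rng.uniform(0.2, 1.0, size=len(orders))
    amps *= spec.boundary_wobble / amps.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(orders))
    pert = np.zeros_like(theta)
    for k, amp, ph in zip(orders, amps, phases):
        pert += amp * np.cos(k * theta + ph)
    r_out = _ellipse_radius(theta, a, b) * (1.0 + pert)

    # wall thickness profile: mean thickness with two gentle harmonics
    w_amps = rng.uniform(0.2, 1.0, size=2)
    w_amps *= spec.wall_wobble / w_amps.sum()
    w_phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    wall = spec.wall_thickness * (
        1.0
        + w_amps[0] * np.cos(2 * theta + w_phases[0])
        + w_amps[1] * np.cos(3 * theta + w_phases[1])
    )
    r_in = r_out - wall

    outer = rho <= r_out
    inner = rho <= r_in
    sat = outer & ~inner

    # spinal island: posterior midline (theta ~ 0), inside the inner region
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    island = np.zeros((n, n), dtype=bool)
    if spec.spinal_island:
        # radius of the inner boundary straight down from the center
        idx_theta0 = np.abs(theta) < 0.05
        r_in0 = float(np.max(rho[idx_theta0 & inner], initial=10.0))
        icr = spec.center[0] + spec.spinal_island_offset * r_in0
        icc = spec.center[1]
        island = (rr - icr) ** 2 + (cc - icc) ** 2 <= spec.spinal_island_radius**2
        island &= inner

    # VAT blobs: random disks sprinkled inside the cavity, away from the island
    vat = np.zeros((n, n), dtype=bool)
    lo, hi = spec.vat_blob_radius_range
    for _ in range(spec.n_vat_blobs):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        frac = np.sqrt(rng.uniform(0.0, 1.0)) * 0.8
        r_here = _ellipse_radius(np.array(ang), a, b) * (1.0 + 0.0) - spec.wall_thickness
        bcr = spec.center[0] + frac * r_here * np.cos(ang)
        bcc = spec.center[1] + frac * r_here * np.sin(ang)
        rad = rng.uniform(lo, hi)
        ar = rng.uniform(0.7, 1.3)  # mild anisotropy
        blob = ((rr - bcr) / (rad * ar)) ** 2 + ((cc - bcc) / rad) ** 2 <= 1.0
        vat |= blob
    vat &= inner
    vat &= ~island

    truth = GroundTruth(outer, inner, sat, vat, island)
    truth.validate()

    fat = truth.fat_mask
    img = np.zeros((n, n), dtype=np.float64)
    img[inner] = spec.tissue_intensity
    img[fat] = spec.fat_intensity

    sl = DixonSlice(
        img,
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        level=spec.level,
    )
    sl = apply_degradation(
        sl,
        noise_sd=spec.noise_sd,
        bias_amplitude=spec.bias_amplitude,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return sl, truth


def _bias_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1-amplitude, 1+amplitude], max-normalized."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    yy = yy / max(h - 1, 1) - 0.5
    xx = xx / max(w - 1, 1) - 0.5
    f = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        kr, kc = rng.uniform(-2.0, 2.0, size=2)  # low spatial frequency, cycles/FOV
        ph = rng.uniform(0.0, 2.0 * np.pi)
        f += rng.uniform(0.3, 1.0) * np.cos(2.0 * np.pi * (kr * yy + kc * xx) + ph)
    peak = np.max(np.abs(f))
    if peak > 0:
        f /= peak
    return 1.0 + amplitude * f


def apply_degradation(
    image: DixonSlice, noise_sd: float, bias_amplitude: float, seed: int
) -> DixonSlice:
    """Degrade a slice with a smooth bias field and additive Gaussian noise.

    The bias field is multiplicative and bounded by ``1 ± bias_amplitude``
    pointwise; the noise is i.i.d. Gaussian with standard deviation
    ``noise_sd``, applied after the bias. Negative results are clipped to
    zero (fat-only magnitude images are non-negative); with intensities
    well above the noise floor the clip never triggers. Zero noise and
    zero bias return the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.0 <= bias_amplitude < 1.0):
        raise ValueError("bias_amplitude must lie in [0, 1)")
    if noise_sd == 0 and bias_amplitude == 0:
        return image.with_intensities(image.intensities.copy())
    rng = np.random.default_rng(seed)
    arr = image.intensities.copy()
    if bias_amplitude > 0:
        arr = arr * _bias_field(arr.shape, bias_amplitude, rng)
    if noise_sd > 0:
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    return image.with_intensities(np.clip(arr, 0.0, None))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def truth_to_labelmap(truth: GroundTruth) -> np.ndarray:
    """Pack a GroundTruth into one integer image (see TRUTH_CODES); lossless."""
    lab = np.zeros(truth.outer_mask.shape, dtype=np.int16)
    lab[truth.inner_mask] = TRUTH_CODES["tissue"]
    lab[truth.sat_mask] = TRUTH_CODES["sat"]
    lab[truth.vat_mask] = TRUTH_CODES["vat"]
    lab[truth.spinal_island_mask] = TRUTH_CODES["spinal_island"]
    return lab


def labelmap_to_truth(lab: np.ndarray) -> GroundTruth:
    """Inverse of :func:`truth_to_labelmap`."""
    lab = np.asarray(lab)
    sat = lab == TRUTH_CODES["sat"]
    vat = lab == TRUTH_CODES["vat"]
    island = lab == TRUTH_CODES["spinal_island"]
    tissue = lab == TRUTH_CODES["tissue"]
    inner = vat | island | tissue
    outer = inner | sat
    return GroundTruth(outer, inner, sat, vat, island)


def visit_counts_for_total(
    n_subjects: int, total_rows: int, n_levels: int = 2
) -> list[int]:
    """Deterministic per-subject visit counts whose scans sum to total_rows.

    Each visit yields ``n_levels`` manifest rows (one slice per disc
    level), so ``total_rows`` must be divisible by ``n_levels`` and at
    least ``n_subjects * n_levels`` (every subject has >= 1 visit).
    """
    if total_rows % n_levels != 0:
        raise ValueError("total_rows must be divisible by the number of levels")
    total_visits = total_rows // n_levels
    if total_visits < n_subjects:
        raise ValueError("need at least one visit per subject")
    base = total_visits // n_subjects
    extra = total_visits - base * n_subjects
    return [base + 1] * extra + [base] * (n_subjects - extra)


DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    # fractions of image_size unless noted
    "semi_axis_row": (0.24, 0.32),
    "semi_axis_col": (0.30, 0.40),
    "wall_thickness": (0.06, 0.12),
    "boundary_wobble": (0.02, 0.08),
    "wall_wobble": (0.10, 0.35),
    "n_vat_blobs": (6, 18),  # integer count
    "visit_drift_sd": (0.02, 0.02),  # relative random-walk step per visit
}


def generate_cohort(
    n_subjects: int,
    visit_count_rule,
    spec_ranges: Optional[dict] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    levels: tuple[str, ...] = LEVELS,
    image_size: int = 384,
    noise_sd: float = 10.0,
    bias_amplitude: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Generate a longitudinal phantom cohort.

    Parameters
    ----------
    n_subjects
        Number of subjects (>= 1).
    visit_count_rule
        Either an int (fixed visits per subject), a list of per-subject
        visit counts (see :func:`visit_counts_for_total`), or a callable
        ``rng -> int``.
    spec_ranges
        Per-parameter ``(low, high)`` ranges for the subject-level base
        geometry draw; merged over :data:`DEFAULT_SPEC_RANGES`.
    seed
        Master seed; fans out to per-image child seeds deterministically.
    out_dir
        If given, images and truth label maps are written there as NIfTI
        and the manifest as ``manifest.csv``; otherwise everything is kept
        in memory.

    Returns
    -------
    manifest : pandas.DataFrame
        Columns ``subject_id, visit, level, seed, image_path, truth_path``;
        one row per generated slice, ``(subject_id, visit, level)`` unique.
    data : dict
        ``(subject_id, visit, level) -> (DixonSlice, GroundTruth)`` for all
        generated slices.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown spec_ranges keys: {sorted(unknown)}")
        ranges.update(spec_ranges)
    for k, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"impossible range for {k}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    if isinstance(visit_count_rule, int):
        counts = [visit_count_rule] * n_subjects
    elif callable(visit_count_rule):
        counts = [int(visit_count_rule(rng)) for _ in range(n_subjects)]
    else:
        counts = [int(c) for c in visit_count_rule]
        if len(counts) != n_subjects:
            raise ValueError("visit count list length must equal n_subjects")
    if any(c < 1 for c in counts):
        raise ValueError("every subject needs >= 1 visit")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    data: dict = {}
    s = float(image_size)
    for i, n_visits in enumerate(counts):
        sid = f"S{i:04d}"
        semi_axes = (
            rng.uniform(*ranges["semi_axis_row"]) * s,
            rng.uniform(*ranges["semi_axis_col"]) * s,
        )
        boundary_wobble = rng.uniform(*ranges["boundary_wobble"])
        wall_wobble = rng.uniform(*ranges["wall_wobble"])
        # keep the wall feasible for this subject's ellipse at any image size
        wall_cap = (min(semi_axes) * (1.0 - boundary_wobble) - 5.0) / (1.0 + wall_wobble)
        wall_floor = 1.0 / max(1e-6, 1.0 - wall_wobble)
        base = {
            "semi_axes": semi_axes,
            "wall_thickness": float(np.clip(
                rng.uniform(*ranges["wall_thickness"]) * s, wall_floor, wall_cap)),
            "boundary_wobble": boundary_wobble,
            "wall_wobble": wall_wobble,
            "n_vat_blobs": int(rng.integers(int(ranges["n_vat_blobs"][0]),
                                            int(ranges["n_vat_blobs"][1]) + 1)),
        }
        drift_sd = ranges["visit_drift_sd"][0]
        for visit in range(n_visits):
            if visit > 0:  # longitudinal random walk on the subject geometry
                ga, gb = base["semi_axes"]
                base["semi_axes"] = (
                    float(np.clip(ga * (1 + rng.normal(0, drift_sd)), 0.20 * s, 0.34 * s)),
                    float(np.clip(gb * (1 + rng.normal(0, drift_sd)), 0.24 * s, 0.42 * s)),
                )
                cap = (min(base["semi_axes"]) * (1.0 - boundary_wobble) - 5.0) / (
                    1.0 + wall_wobble)
                base["wall_thickness"] = float(
                    np.clip(base["wall_thickness"] * (1 + rng.normal(0, 2 * drift_sd)),
                            wall_floor, min(0.13 * s, cap))
                )
            for level in levels:
                child_seed = int(rng.integers(0, 2**31 - 1))
                spec = PhantomSpec(
                    image_size=image_size,
                    semi_axes=base["semi_axes"],
                    wall_thickness=base["wall_thickness"],
                    boundary_wobble=base["boundary_wobble"],
                    wall_wobble=base["wall_wobble"],
                    n_vat_blobs=base["n_vat_blobs"] + (2 if level == "L45" else 0),
                    noise_sd=noise_sd,
                    bias_amplitude=bias_amplitude,
                    level=level,
                )
                sl, truth = generate_phantom(spec, child_seed)
                sl.subject_id, sl.visit = sid, visit
                key = (sid, visit, level)
                data[key] = (sl, truth)
                img_path = truth_path = ""
                if out_path is not None:
                    from . import image_io

                    stem = f"{sid}_v{visit}_{level}"
                    img_path = str(out_path / f"{stem}_img.nii.gz")
                    truth_path = str(out_path / f"{stem}_truth.nii.gz")
                    image_io.write_image(img_path, sl)
                    image_io.write_labelmap(truth_path, truth_to_labelmap(truth))
                rows.append(
                    {
                        "subject_id": sid,
                        "visit": visit,
                        "level": level,
                        "seed": child_seed,
                        "image_path": img_path,
                        "truth_path": truth_path,
                    }
                )
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest, data
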