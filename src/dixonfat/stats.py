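"""Agreement evaluation: Dice overlap, areas, Pearson, Bland–Altman,
paired t-test, and the subject-disjoint fivefold cross-validation harness.

All statistics follow the conventions used for method-agreement studies:
the Dice similarity coefficient DSC = 2|A∩B| / (|A|+|B|) per class, Pearson
product-moment correlation of areas, Bland–Altman bias and limits of
agreement (mean ± 1.96 · SD of the paired differences, sample SD with the
n−1 denominator), and a two-sided paired Student's t-test. Cross-validation
is split by subject so that repeated scans of one participant never appear
in both the training and the test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FourClassLabelMap

__all__ = [
    "dice",
    "pearson",
    "bland_altman",
    "paired_ttest",
    "BlandAltman",
    "FoldSplit",
    "make_folds",
    "crossval",
    "area_summary",
    "AgreementReport",
    "agreement_report",
]

CLASSES = ("outer", "inner", "sat", "vat")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks count as perfect agreement (1.0) by convention —
    relevant because some slices contain no visceral fat at all.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.sum(xc * yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    means: np.ndarray


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bland–Altman agreement: bias and 95% limits of agreement.

    diffs = x − y; bias = mean(diffs); limits = bias ± 1.96 · SD(diffs)
    with the sample (n−1) standard deviation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        diffs=diffs,
        means=(x + y) / 2.0,
    )


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student's t-test; returns (t, p).

    Degenerate all-zero differences (x identical to y) are reported as
    (t=0, p=1): no evidence of a systematic difference.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return t, p


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Subject → fold assignment for k-fold cross-validation."""

    k: int
    assignment: dict[str, int]
    seed: int

    def subjects_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def validate(self) -> None:
        folds = np.array(list(self.assignment.values()))
        if set(np.unique(folds)) - set(range(self.k)):
            raise ValueError("fold index out of range")
        sizes = np.bincount(folds, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than one subject")


def make_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldSplit:
    """Partition subjects into k near-equal folds (subject-level split).

    All scans of a subject share one fold, preventing longitudinal leakage
    between training and test sets.
    """
    subjects = sorted(manifest["subject_id"].unique())
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[idx]: i % k for i, idx in enumerate(order)}
    split = FoldSplit(k=k, assignment=assignment, seed=seed)
    split.validate()
    return split


def crossval(
    manifest: pd.DataFrame,
    train_fn: Callable[[pd.DataFrame, int], object],
    eval_fn: Callable[[object, pd.DataFrame], pd.DataFrame],
    k: int = 5,
    seed: int = 0,
) -> "AgreementReport":
    """k-fold cross-validation: train on k−1 folds, evaluate the held-out one.

    ``train_fn(train_manifest, fold_seed)`` returns a fitted model;
    ``eval_fn(model, test_manifest)`` returns a per-image DataFrame with at
    least columns ``subject_id, visit, level`` plus per-class ``dsc_*`` and
    area columns. Per-fold results are averaged with equal fold weight for
    the aggregate, matching fold-averaged reporting.
    """
    split = make_folds(manifest, k=k, seed=seed)
    per_image_frames = []
    for fold in range(k):
        test_subjects = set(split.subjects_in_fold(fold))
        test_m = manifest[manifest["subject_id"].isin(test_subjects)]
        train_m = manifest[~manifest["subject_id"].isin(test_subjects)]
        model = train_fn(train_m, seed + 1000 + fold)
        df = eval_fn(model, test_m).copy()
        df["fold"] = fold
        per_image_frames.append(df)
    per_image = pd.concat(per_image_frames, ignore_index=True)
    return agreement_report(per_image, k=k)


# ---------------------------------------------------------------------------
# areas and report assembly
# ---------------------------------------------------------------------------

def area_summary(labels: FourClassLabelMap,
                 spacing_mm: Optional[tuple[float, float]] = None) -> dict[str, float]:
    """Per-class areas (pixels and cm²) and trunk-relative fat ratios.

    area_cm² = pixels × spacing_row × spacing_col / 100. Ratios express
    fat burden relative to the trunk cross-section: SAT / outer area,
    VAT / inner area, and (SAT+VAT) / outer area; they are invariant to a
    uniform change of pixel spacing.
    """
    if spacing_mm is None:
        spacing_mm = labels.pixel_spacing_mm
    sr, sc = spacing_mm
    if sr <= 0 or sc <= 0:
        raise ValueError("pixel spacing must be positive")
    px_cm2 = sr * sc / 100.0
    counts = {
        "outer": int(labels.regions.outer_mask.sum()),
        "inner": int(labels.regions.inner_mask.sum()),
        "sat": int(labels.sat_mask.sum()),
        "vat": int(labels.vat_mask.sum()),
    }
    out: dict[str, float] = {}
    for k, n in counts.items():
        out[f"{k}_pixels"] = n
        out[f"{k}_cm2"] = n * px_cm2
    out["sat_over_outer"] = counts["sat"] / counts["outer"] if counts["outer"] else 0.0
    out["vat_over_inner"] = counts["vat"] / counts["inner"] if counts["inner"] else 0.0
    out["fat_over_outer"] = (
        (counts["sat"] + counts["vat"]) / counts["outer"] if counts["outer"] else 0.0
    )
    return out


@dataclass
class AgreementReport:
    """Per-image and aggregate agreement between prediction and reference."""

    per_image: pd.DataFrame
    dsc_mean: dict[str, float]
    dsc_sd: dict[str, float]
    per_fold_dsc: dict[str, list[float]]
    per_level: dict[str, dict[str, float]]
    pearson_r: dict[str, float] = field(default_factory=dict)
    bland_altman: dict[str, BlandAltman] = field(default_factory=dict)
    ttest: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "dsc_mean": self.dsc_mean,
            "dsc_sd": self.dsc_sd,
            "per_fold_dsc": self.per_fold_dsc,
            "per_level": self.per_level,
            "pearson_r": self.pearson_r,
            "bland_altman": {
                k: {"bias": v.bias, "loa_low": v.loa_low, "loa_high": v.loa_high}
                for k, v in self.bland_altman.items()
            },
            "ttest": {k: {"t": v[0], "p": v[1]} for k, v in self.ttest.items()},
            "n_images": int(len(self.per_image)),
        }
        return out


def agreement_report(per_image: pd.DataFrame, k: Optional[int] = None) -> AgreementReport:
    """Aggregate a per-image results table into an AgreementReport.

    Expects columns ``dsc_<class>`` for each class present, optionally
    ``fold``, ``level``, and paired area columns ``<class>_cm2_pred`` /
    ``<class>_cm2_ref`` for correlation/agreement statistics.
    """
    dsc_cols = [c for c in per_image.columns if c.startswith("dsc_")]
    classes = [c[len("dsc_"):] for c in dsc_cols]
    dsc_mean = {cl: float(per_image[f"dsc_{cl}"].mean()) for cl in classes}
    dsc_sd = {
        cl: float(per_image[f"dsc_{cl}"].std(ddof=1)) if len(per_image) > 1 else 0.0
        for cl in classes
    }
    per_fold: dict[str, list[float]] = {}
    if "fold" in per_image.columns:
        nfolds = k if k is not None else int(per_image["fold"].max()) + 1
        for cl in classes:
            per_fold[cl] = [
                float(per_image.loc[per_image["fold"] == f, f"dsc_{cl}"].mean())
                for f in range(nfolds)
            ]
        # fold-averaged aggregate: unweighted mean of the per-fold means
        dsc_mean = {cl: float(np.mean(per_fold[cl])) for cl in classes}
    per_level: dict[str, dict[str, float]] = {}
    if "level" in per_image.columns:
        for lvl, grp in per_image.groupby("level"):
            per_level[str(lvl)] = {
                **{cl: float(grp[f"dsc_{cl}"].mean()) for cl in classes},
                "n_images": int(len(grp)),
            }
    report = AgreementReport(
        per_image=per_image,
        dsc_mean=dsc_mean,
        dsc_sd=dsc_sd,
        per_fold_dsc=per_fold,
        per_level=per_level,
    )
    for cl in classes:
        pc, rc = f"{cl}_cm2_pred", f"{cl}_cm2_ref"
        if pc in per_image.columns and rc in per_image.columns and len(per_image) >= 3:
            x = per_image[pc].to_numpy(float)
            y = per_image[rc].to_numpy(float)
            try:
                report.pearson_r[cl] = pearson(x, y)
            except ValueError:
                pass
            report.bland_altman[cl] = bland_altman(x, y)
            report.ttest[cl] = paired_ttest(x, y)
    return report


def plot_agreement(report: AgreementReport, out_dir, classes: Optional[list[str]] = None):
    """Scatter (prediction vs reference) and Bland–Altman panels as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = classes or list(report.bland_altman)
    for cl in classes:
        ba = report.bland_altman[cl]
        x = report.per_image[f"{cl}_cm2_ref"].to_numpy(float)
        y = report.per_image[f"{cl}_cm2_pred"].to_numpy(float)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(x, y, s=12)
        lim = [0, max(x.max(), y.max()) * 1.05 + 1e-9]
        axes[0].plot(lim, lim, "k--", lw=0.8)
        r = report.pearson_r.get(cl, float("nan"))
        axes[0].set(xlabel="reference area (cm²)", ylabel="computer area (cm²)",
                    title=f"{cl.upper()}  r = {r:.3f}")
        axes[1].scatter(ba.means, ba.diffs, s=12)
        axes[1].axhline(ba.bias, ls="--", color="k")
        axes[1].axhline(ba.loa_low, ls=":", color="k")
        axes[1].axhline(ba.loa_high, ls=":", color="k")
        axes[1].set(xlabel="mean of methods (cm²)", ylabel="difference (cm²)",
                    title=f"bias {ba.bias:+.2f}  LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
        fig.tight_layout()
        fig.savefig(out / f"agreement_{cl}.png", dpi=120)
        plt.close(fig)
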