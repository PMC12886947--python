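"""Left-atrial volumetrics, the 2D biplane comparator, method-agreement
statistics and segmentation-overlap metrics.

Volumes from the 3-D segmentation are plain voxel counts; the clinical
comparator is the biplane disk-summation estimate built from paired
two-chamber/four-chamber diameters. Agreement between the two is quantified
with Pearson correlation (Fisher-z confidence interval) and Bland-Altman
bias / 95% limits of agreement. Dice and HD95 compare segmentation masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .flowdata import Mask3D


@dataclass
class SubjectBody:
    weight: float   # kg
    height: float   # cm

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")


@dataclass
class AgreementResult:
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    r_undefined: bool = False


def mask_volume(mask: Mask3D, label: str | int = "LA") -> float:
    """Volume of one labeled region in ml (voxel count x voxel volume)."""
    region = mask.region(label)
    if not region.any():
        warnings.warn(f"label {label!r} selects no voxels; volume is 0")
        return 0.0
    return float(region.sum()) * mask.voxel_volume_mm3 * 1e-3


def dubois_bsa(body: SubjectBody) -> float:
    """DuBois body surface area in m^2: 0.007184 * W^0.425 * H^0.725."""
    return 0.007184 * body.weight ** 0.425 * body.height ** 0.725


def lav_indexed(volume_ml: float, body: SubjectBody) -> float:
    """Left-atrial volume indexed to DuBois body surface area, ml/m^2."""
    return volume_ml / dubois_bsa(body)


def biplane_disk_volume(diam_2ch, diam_4ch, long_axis_mm: float) -> float:
    """Biplane disk-summation volume in ml.

    V = (pi/4) * sum_i a_i * b_i * (L / N) with paired elliptical disk
    diameters a_i (2-chamber) and b_i (4-chamber), all in mm.
    """
    a = np.asarray(diam_2ch, dtype=float)
    b = np.asarray(diam_4ch, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"diameter lists differ in length: "
                         f"{a.size} vs {b.size}")
    if a.size < 1:
        raise ValueError("need at least one disk")
    return float(np.pi / 4.0 * np.sum(a * b) * (long_axis_mm / a.size) * 1e-3)


def agreement(pairs, confidence: float = 0.95) -> AgreementResult:
    """Pearson correlation and Bland-Altman agreement between paired methods.

    ``pairs`` is a sequence of (x, y). Differences are y - x; the limits of
    agreement are bias +- 1.96 * sample SD of the differences.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in one method; Pearson r undefined")
        return AgreementResult(np.nan, np.nan, np.nan, bias, loa_low,
                               loa_high, d, r_undefined=True)
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if abs(r) == 1.0 or n <= 3:
        lo = hi = r
    else:
        zr = np.arctanh(r)
        zc = stats.norm.ppf(0.5 + confidence / 2)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(zr - zc * se), np.tanh(zr + zc * se)
    return AgreementResult(r, float(lo), float(hi), bias, loa_low, loa_high, d)


def dice(mask_a: Mask3D, mask_b: Mask3D, label: str | int = "LA") -> float:
    """Dice overlap 2|A^B| / (|A|+|B|); both-empty is defined as 1."""
    a = mask_a.region(label)
    b = mask_b.region(label)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _surface_points_mm(region: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(region)
    surf = region & ~eroded
    kk, jj, ii = np.nonzero(surf)
    return np.stack([ii * spacing[0], jj * spacing[1], kk * spacing[2]],
                    axis=1)


def hd95(mask_a: Mask3D, mask_b: Mask3D, label: str | int = "LA") -> float:
    """95th percentile of pooled symmetric surface-to-surface distances (mm).

    Surfaces are the voxel shells of each region; distances are measured in
    both directions, pooled, and the 95th percentile is taken with linear
    interpolation.
    """
    a = mask_a.region(label)
    b = mask_b.region(label)
    if not a.any() or not b.any():
        raise ValueError("HD95 requires both masks to be non-empty")
    pa = _surface_points_mm(a, mask_a.spacing)
    pb = _surface_points_mm(b, mask_b.spacing)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
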