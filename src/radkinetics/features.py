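"""IBSI-style radiomics features on a masked HU volume.

The bank covers four families — grey-level co-occurrence (GLCM),
grey-level run length (GLRLM), first-order intensity statistics, and
intensity-histogram features — each texture family in both a 2-D
slice-averaged and a full 3-D variant.  The default configuration
yields 123 named features.

Aggregation conventions
-----------------------
* 2-D: one matrix per (axial slice, in-plane direction); the feature is
  computed on every matrix and averaged ("averaged" aggregation).
* 3-D: a single matrix accumulated over the 13 unique 3-D directions.
* GLCM matrices are symmetrised and normalised to joint probabilities.
* Degenerate single-grey-level regions return the analytic limit of each
  feature (e.g. information correlation 1 -> 0, normalised grey-level
  non-uniformity -> 1) rather than NaN, so feature trajectories remain
  numeric over fractions in which the gland is homogeneous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyROIError, UndefinedTextureError
from .preprocess import ImageSeries

logger = logging.getLogger(__name__)

# directions as (dz, dy, dx) voxel offsets; first non-zero component positive
DIRECTIONS_2D = [(0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1)]
DIRECTIONS_3D = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

_EPS = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# discretisation

@dataclass(frozen=True)
class DiscretizationSpec:
    """Grey-level discretisation: ``fixed_bin_number`` (value = number of
    bins Ng) or ``fixed_bin_size`` (value = bin width in HU)."""

    method: str = "fixed_bin_number"
    value: float = 32

    def __post_init__(self) -> None:
        if self.method not in ("fixed_bin_number", "fixed_bin_size"):
            raise ValueError(f"unknown discretisation method {self.method!r}")
        if self.value <= 0:
            raise ValueError("discretisation parameter must be positive")


@dataclass
class GreyLevelVolume:
    """Integer grey levels 1..ng on masked voxels; 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    spec: DiscretizationSpec
    bin_edges: np.ndarray

    def bin_centre(self, level: int) -> float:
        return float(0.5 * (self.bin_edges[level - 1] + self.bin_edges[level]))


def discretize(volume: np.ndarray, mask: np.ndarray,
               spec: DiscretizationSpec = DiscretizationSpec()) -> GreyLevelVolume:
    """Map masked HU values to integer grey levels 1..Ng.

    Fixed bin number: ``level = min(Ng, 1 + floor(Ng * (x - min)/(max - min)))``.
    Fixed bin size w: ``level = 1 + floor((x - min)/w)``.
    A constant region collapses to a single level (Ng effective = 1).
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise EmptyROIError("cannot discretise an empty mask")
    vals = volume[mask].astype(float)
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        edges = np.array([vmin - 0.5, vmin + 0.5])
        return GreyLevelVolume(levels, mask, 1, spec, edges)
    if spec.method == "fixed_bin_number":
        ng = int(spec.value)
        lv = np.minimum(ng, 1 + np.floor(ng * (vals - vmin) / (vmax - vmin))).astype(np.int32)
        edges = vmin + (vmax - vmin) * np.arange(ng + 1) / ng
    else:
        w = float(spec.value)
        lv = (1 + np.floor((vals - vmin) / w)).astype(np.int32)
        ng = int(lv.max())
        edges = vmin + w * np.arange(ng + 1)
    levels[mask] = lv
    return GreyLevelVolume(levels, mask, ng, spec, edges)


# ---------------------------------------------------------------------------
# co-occurrence matrices

@dataclass
class CooccurrenceMatrix:
    """Stack of symmetric joint-probability matrices.

    ``matrices`` has shape (M, Ng, Ng): M = slice x direction matrices in
     2-D averaged mode, M = 1 in 3-D mode.  Each matrix sums to one.
    """

    matrices: np.ndarray
    distance: int
    mode: str

    def __post_init__(self) -> None:
        sums = self.matrices.sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise UndefinedTextureError("co-occurrence matrices must sum to 1")


def _offset_pairs(levels: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """Grey-level pairs (a, b) and the slice index of a, for one offset."""
    dz, dy, dx = off
    sl_a, sl_b = [], []
    for d, n in zip((dz, dy, dx), levels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    a = levels[sl_a][valid]
    b = levels[sl_b][valid]
    z = np.nonzero(valid)[0] if dz == 0 else None  # slice of voxel a (2-D only)
    if z is not None:
        z = np.repeat(np.arange(valid.shape[0]), valid.sum(axis=(1, 2)))
    return a, b, z


def glcm(grey: GreyLevelVolume, distance: int = 1, mode: str = "2d_avg") -> CooccurrenceMatrix:
    """Build symmetric grey-level co-occurrence matrices.

    ``mode='2d_avg'``: one matrix per (slice, in-plane direction) with at
    least one voxel pair; ``mode='3d'``: a single matrix accumulated over
    the 13 unique 3-D directions.
    """
    ng = grey.ng
    nz = grey.levels.shape[0]
    if mode == "2d_avg":
        mats = np.zeros((nz * len(DIRECTIONS_2D), ng, ng))
        for di, (dz, dy, dx) in enumerate(DIRECTIONS_2D):
            off = (dz * distance, dy * distance, dx * distance)
            a, b, z = _offset_pairs(grey.levels, grey.mask, off)
            if a.size == 0:
                continue
            idx = z * ng * ng + (a - 1) * ng + (b - 1)
            counts = np.bincount(idx, minlength=nz * ng * ng).reshape(nz, ng, ng)
            mats[di * nz:(di + 1) * nz] = counts
        mats = mats + mats.transpose(0, 2, 1)  # symmetrise
        sums = mats.sum(axis=(1, 2))
        keep = sums > 0
        if not keep.any():
            raise UndefinedTextureError("no valid voxel pairs for GLCM")
        mats = mats[keep] / sums[keep][:, None, None]
        return CooccurrenceMatrix(mats, distance, mode)
    if mode == "3d":
        mat = np.zeros((ng, ng))
        for dz, dy, dx in DIRECTIONS_3D:
            off = (dz * distance, dy * distance, dx * distance)
            a, b, _ = _offset_pairs(grey.levels, grey.mask, off)
            if a.size == 0:
                continue
            np.add.at(mat, (a - 1, b - 1), 1.0)
        mat = mat + mat.T
        if mat.sum() == 0:
            raise UndefinedTextureError("no valid voxel pairs for GLCM")
        mat = mat / mat.sum()
        return CooccurrenceMatrix(mat[None, :, :], distance, mode)
    raise ValueError(f"unknown GLCM mode {mode!r}")


def _glcm_stack_features(P: np.ndarray) -> dict[str, np.ndarray]:
    """All GLCM features evaluated on a stack of matrices (M, Ng, Ng)."""
    m, ng, _ = P.shape
    i = np.arange(1, ng + 1)
    I = i[None, :, None] * np.ones((1, 1, ng))
    J = i[None, None, :] * np.ones((1, ng, 1))
    px = P.sum(axis=2)          # (M, Ng) marginal of i
    py = P.sum(axis=1)
    mu_x = (px * i).sum(axis=1)
    mu_y = (py * i).sum(axis=1)
    sd_x = np.sqrt((px * (i - mu_x[:, None]) ** 2).sum(axis=1))
    sd_y = np.sqrt((py * (i - mu_y[:, None]) ** 2).sum(axis=1))

    def esum(arr):
        return arr.sum(axis=(1, 2))

    def xlog2(p):
        return np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0)

    out: dict[str, np.ndarray] = {}
    out["joint_max"] = P.max(axis=(1, 2))
    mu = esum(I * P)
    out["joint_average"] = mu
    out["joint_variance"] = esum((I - mu[:, None, None]) ** 2 * P)
    hxy = -esum(xlog2(P))
    out["joint_entropy"] = hxy
    out["energy"] = esum(P ** 2)
    out["contrast"] = esum((I - J) ** 2 * P)
    out["dissimilarity"] = esum(np.abs(I - J) * P)
    out["inverse_difference"] = esum(P / (1.0 + np.abs(I - J)))
    out["inverse_difference_norm"] = esum(P / (1.0 + np.abs(I - J) / ng))
    out["inverse_difference_moment"] = esum(P / (1.0 + (I - J) ** 2))
    out["inverse_difference_moment_norm"] = esum(P / (1.0 + ((I - J) / ng) ** 2))
    offd = (I != J)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(offd, 1.0 / np.maximum((I - J) ** 2, 1), 0.0)
    out["inverse_variance"] = esum(P * inv * offd)
    denom = sd_x * sd_y
    corr = np.where(denom > 0, (esum(I * J * P) - mu_x * mu_y) / np.maximum(denom, _EPS), 0.0)
    out["correlation"] = corr
    out["autocorrelation"] = esum(I * J * P)
    cshift = I + J - mu_x[:, None, None] - mu_y[:, None, None]
    out["cluster_tendency"] = esum(cshift ** 2 * P)
    out["cluster_shade"] = esum(cshift ** 3 * P)
    out["cluster_prominence"] = esum(cshift ** 4 * P)

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(ng)                  # |i-j| = 0..ng-1
    k_sum = np.arange(2, 2 * ng + 1)        # i+j = 2..2ng
    p_diff = np.zeros((m, ng))
    p_sum = np.zeros((m, 2 * ng - 1))
    absdiff = np.abs(i[:, None] - i[None, :])
    sums_ij = i[:, None] + i[None, :]
    for k in k_diff:
        p_diff[:, k] = (P * (absdiff == k)).sum(axis=(1, 2))
    for n_, k in enumerate(k_sum):
        p_sum[:, n_] = (P * (sums_ij == k)).sum(axis=(1, 2))
    da = (p_diff * k_diff).sum(axis=1)
    out["difference_average"] = da
    out["difference_variance"] = (p_diff * (k_diff - da[:, None]) ** 2).sum(axis=1)
    out["difference_entropy"] = -(xlog2(p_diff)).sum(axis=1)
    sa = (p_sum * k_sum).sum(axis=1)
    out["sum_average"] = sa
    out["sum_variance"] = (p_sum * (k_sum - sa[:, None]) ** 2).sum(axis=1)
    out["sum_entropy"] = -(xlog2(p_sum)).sum(axis=1)

    # information correlations; convention: single grey level -> 0
    hx = -(xlog2(px)).sum(axis=1)
    hy = -(xlog2(py)).sum(axis=1)
    pxy_ind = px[:, :, None] * py[:, None, :]
    hxy1 = -esum(np.where(P > 0, P * np.log2(np.maximum(pxy_ind, _EPS)), 0.0))
    hxy2 = -esum(xlog2(pxy_ind))
    hmax = np.maximum(hx, hy)
    out["info_corr_1"] = np.where(hmax > 0, (hxy - hxy1) / np.maximum(hmax, _EPS), 0.0)
    with np.errstate(over="ignore"):
        imc2_arg = 1.0 - np.exp(-2.0 * np.log(2.0) * np.maximum(hxy2 - hxy, 0.0))
    out["info_corr_2"] = np.sqrt(np.clip(imc2_arg, 0.0, 1.0))
    return out


GLCM_FEATURES = [
    "joint_max", "joint_average", "joint_variance", "joint_entropy", "energy",
    "contrast", "dissimilarity", "inverse_difference", "inverse_difference_norm",
    "inverse_difference_moment", "inverse_difference_moment_norm",
    "inverse_variance", "correlation", "autocorrelation", "cluster_tendency",
    "cluster_shade", "cluster_prominence", "difference_average",
    "difference_variance", "difference_entropy", "sum_average", "sum_variance",
    "sum_entropy", "info_corr_1", "info_corr_2",
]


def glcm_features(P: CooccurrenceMatrix) -> dict[str, float]:
    """Feature values of one GLCM object: computed per matrix, averaged."""
    per_mat = _glcm_stack_features(P.matrices)
    return {name: float(np.mean(per_mat[name])) for name in GLCM_FEATURES}


def glcm_information_correlation_1(P: CooccurrenceMatrix) -> float:
    """Information correlation 1: (HXY - HXY1) / max(HX, HY), in [-1, 0].

    Entropies use log base 2 with the 0*log(0)=0 convention; a single
    grey level (max marginal entropy zero) returns 0.
    """
    return glcm_features(P)["info_corr_1"]


# ---------------------------------------------------------------------------
# run-length matrices

@dataclass
class RunLengthMatrix:
    """Stack of run-length count matrices.

    ``counts`` has shape (M, Ng, Nr): counts of maximal runs of grey
    level i (rows) and length l (columns, 1-based).  ``n_voxels`` holds
    the voxel count of each matrix's region (for run percentage).
    """

    counts: np.ndarray
    n_voxels: np.ndarray
    mode: str

    @property
    def ns(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))


def _shift(arr: np.ndarray, off: tuple[int, int, int], fill):
    out = np.full_like(arr, fill)
    src, dst = [], []
    for d, n in zip(off, arr.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _runs_for_direction(levels: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """Maximal runs along one direction: (grey, length, start-slice) arrays.

    Dynamic programme: forward run counts propagate backwards from each
    run's tail, converging after max-run-length iterations.
    """
    same_next = (levels == _shift(levels, tuple(-o for o in off), fill=-1)) & mask
    same_prev = (levels == _shift(levels, off, fill=-1)) & mask
    starts = mask & ~same_prev
    f = np.ones(levels.shape, dtype=np.int32)
    max_len = int(np.ceil(np.sqrt(sum((o * n) ** 2 for o, n in zip(off, levels.shape)))))
    for _ in range(min(max_len, max(levels.shape))):
        shifted = _shift(f, tuple(-o for o in off), fill=0)
        new = np.where(same_next, 1 + shifted, 1)
        if np.array_equal(new, f):
            break
        f = new
    zz = np.nonzero(starts)[0]
    return levels[starts], f[starts], zz


def glrlm(grey: GreyLevelVolume, mode: str = "2d_avg") -> RunLengthMatrix:
    """Build grey-level run-length matrices (runs within the mask only).

    2-D averaged mode yields one matrix per (slice, in-plane direction);
    3-D mode accumulates runs over the 13 unique directions into one.
    """
    if not grey.mask.any():
        raise EmptyROIError("cannot build GLRLM on an empty mask")
    ng = grey.ng
    nz = grey.levels.shape[0]
    nr = int(max(grey.levels.shape))
    vox_per_slice = grey.mask.sum(axis=(1, 2))
    if mode == "2d_avg":
        counts = np.zeros((nz * len(DIRECTIONS_2D), ng, nr))
        for di, off in enumerate(DIRECTIONS_2D):
            g, ln, z = _runs_for_direction(grey.levels, grey.mask, off)
            if g.size == 0:
                continue
            np.add.at(counts, (di * nz + z, g - 1, ln - 1), 1.0)
        nv = np.tile(vox_per_slice, len(DIRECTIONS_2D)).astype(float)
        keep = counts.sum(axis=(1, 2)) > 0
        return RunLengthMatrix(counts[keep], nv[keep], mode)
    if mode == "3d":
        counts = np.zeros((1, ng, nr))
        for off in DIRECTIONS_3D:
            g, ln, _ = _runs_for_direction(grey.levels, grey.mask, off)
            if g.size:
                np.add.at(counts, (np.zeros(g.size, dtype=int), g - 1, ln - 1), 1.0)
        return RunLengthMatrix(counts, np.array([float(grey.mask.sum())]), mode)
    raise ValueError(f"unknown GLRLM mode {mode!r}")


GLRLM_FEATURES = [
    "short_run_emphasis", "long_run_emphasis", "low_grey_run_emphasis",
    "high_grey_run_emphasis", "short_run_low_grey_emphasis",
    "short_run_high_grey_emphasis", "long_run_low_grey_emphasis",
    "long_run_high_grey_emphasis", "grey_level_nonuniformity",
    "norm_grey_level_nonuniformity", "run_length_nonuniformity",
    "norm_run_length_nonuniformity", "run_percentage", "grey_level_variance",
    "run_length_variance", "run_entropy",
]


def _glrlm_stack_features(R: RunLengthMatrix) -> dict[str, np.ndarray]:
    counts = R.counts
    m, ng, nr = counts.shape
    ns = np.maximum(R.ns, _EPS)
    i = np.arange(1, ng + 1, dtype=float)
    l = np.arange(1, nr + 1, dtype=float)
    r_i = counts.sum(axis=2)
    r_l = counts.sum(axis=1)
    out: dict[str, np.ndarray] = {}
    out["short_run_emphasis"] = (r_l / l ** 2).sum(axis=1) / ns
    out["long_run_emphasis"] = (r_l * l ** 2).sum(axis=1) / ns
    out["low_grey_run_emphasis"] = (r_i / i ** 2).sum(axis=1) / ns
    out["high_grey_run_emphasis"] = (r_i * i ** 2).sum(axis=1) / ns
    out["short_run_low_grey_emphasis"] = (counts / (i[:, None] ** 2 * l[None, :] ** 2)).sum(axis=(1, 2)) / ns
    out["short_run_high_grey_emphasis"] = (counts * i[:, None] ** 2 / l[None, :] ** 2).sum(axis=(1, 2)) / ns
    out["long_run_low_grey_emphasis"] = (counts * l[None, :] ** 2 / i[:, None] ** 2).sum(axis=(1, 2)) / ns
    out["long_run_high_grey_emphasis"] = (counts * i[:, None] ** 2 * l[None, :] ** 2).sum(axis=(1, 2)) / ns
    out["grey_level_nonuniformity"] = (r_i ** 2).sum(axis=1) / ns
    out["norm_grey_level_nonuniformity"] = (r_i ** 2).sum(axis=1) / ns ** 2
    out["run_length_nonuniformity"] = (r_l ** 2).sum(axis=1) / ns
    out["norm_run_length_nonuniformity"] = (r_l ** 2).sum(axis=1) / ns ** 2
    out["run_percentage"] = ns / np.maximum(R.n_voxels, 1.0)
    p_i = r_i / ns[:, None]
    p_l = r_l / ns[:, None]
    mu_i = (p_i * i).sum(axis=1)
    mu_l = (p_l * l).sum(axis=1)
    out["grey_level_variance"] = (p_i * (i - mu_i[:, None]) ** 2).sum(axis=1)
    out["run_length_variance"] = (p_l * (l - mu_l[:, None]) ** 2).sum(axis=1)
    p = counts / ns[:, None, None]
    out["run_entropy"] = -np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0).sum(axis=(1, 2))
    return out


def glrlm_features(R: RunLengthMatrix) -> dict[str, float]:
    per_mat = _glrlm_stack_features(R)
    return {name: float(np.mean(per_mat[name])) for name in GLRLM_FEATURES}


def glrlm_norm_grey_level_nonuniformity(R: RunLengthMatrix) -> float:
    """Normalised grey-level non-uniformity: sum_i (sum_l r(i,l))^2 / Ns^2.

    Lies in (0, 1]; equals 1 iff every run shares one grey level.
    """
    ns = R.ns
    if np.any(ns == 0):
        raise UndefinedTextureError("GLNUN undefined for an empty run matrix")
    return glrlm_features(R)["norm_grey_level_nonuniformity"]


# ---------------------------------------------------------------------------
# first-order intensity statistics (raw HU)

STAT_FEATURES = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "iqr_hu", "range", "mean_abs_deviation",
    "robust_mean_abs_deviation", "median_abs_deviation",
    "coefficient_of_variation", "quartile_coefficient", "energy",
    "root_mean_square",
]


def intensity_statistics(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the raw HU values inside the mask.

    Quartiles use linear interpolation between order statistics.
    Skewness/kurtosis are population-moment based (kurtosis is excess);
    both are 0 for a constant region.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EmptyROIError("no masked voxels")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    p10, p90 = np.percentile(v, [10, 90])
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    out = {
        "mean": mean,
        "variance": var,
        "skewness": float(stats.skew(v)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v)) if sd > 0 else 0.0,
        "median": float(q2),
        "minimum": float(v.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(v.max()),
        "iqr_hu": float(q3 - q1),
        "range": float(v.max() - v.min()),
        "mean_abs_deviation": float(np.abs(v - mean).mean()),
        "median_abs_deviation": float(np.abs(v - q2).mean()),
        "coefficient_of_variation": float(sd / mean) if mean != 0 else 0.0,
        "quartile_coefficient": float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0,
        "energy": float((v ** 2).sum()),
        "root_mean_square": float(np.sqrt((v ** 2).mean())),
    }
    robust = v[(v >= p10) & (v <= p90)]
    rmean = robust.mean() if robust.size else mean
    out["robust_mean_abs_deviation"] = float(np.abs(robust - rmean).mean()) if robust.size else 0.0
    return {k: out[k] for k in STAT_FEATURES}


# ---------------------------------------------------------------------------
# intensity-histogram features (discretised levels)

HIST_FEATURES = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "mode", "iqr", "range", "mean_abs_deviation",
    "robust_mean_abs_deviation", "median_abs_deviation",
    "coefficient_of_variation", "quartile_coefficient", "entropy",
    "uniformity", "max_gradient", "max_gradient_intensity_hu",
    "min_gradient", "min_gradient_intensity_hu",
]


def _histogram_gradient(counts: np.ndarray) -> np.ndarray:
    """Finite-difference gradient of histogram counts by grey level:
    one-sided at the boundaries, central in the interior."""
    n = counts.astype(float)
    if n.size == 1:
        return np.zeros(1)
    grad = np.empty_like(n)
    grad[0] = n[1] - n[0]
    grad[-1] = n[-1] - n[-2]
    if n.size > 2:
        grad[1:-1] = (n[2:] - n[:-2]) / 2.0
    return grad


def histogram_features(grey: GreyLevelVolume) -> dict[str, float]:
    """Intensity-histogram features on the discretised grey levels.

    Gradient-extremum intensities are reported in HU (the centre of the
    corresponding discretisation bin); everything else is in grey-level
    units.  The mode takes the smallest level on ties.
    """
    lv = grey.levels[grey.mask].astype(float)
    if lv.size == 0:
        raise EmptyROIError("no masked voxels")
    counts = np.bincount(grey.levels[grey.mask], minlength=grey.ng + 1)[1:]
    base = intensity_statistics(lv)
    p = counts / counts.sum()
    grad = _histogram_gradient(counts)
    gmax = int(np.argmax(grad))
    gmin = int(np.argmin(grad))
    out = {
        "mean": base["mean"],
        "variance": base["variance"],
        "skewness": base["skewness"],
        "kurtosis": base["kurtosis"],
        "median": base["median"],
        "minimum": base["minimum"],
        "p10": base["p10"],
        "p90": base["p90"],
        "maximum": base["maximum"],
        "mode": float(np.argmax(counts) + 1),
        "iqr": base["iqr_hu"],
        "range": base["range"],
        "mean_abs_deviation": base["mean_abs_deviation"],
        "robust_mean_abs_deviation": base["robust_mean_abs_deviation"],
        "median_abs_deviation": base["median_abs_deviation"],
        "coefficient_of_variation": base["coefficient_of_variation"],
        "quartile_coefficient": base["quartile_coefficient"],
        "entropy": float(-np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0).sum()),
        "uniformity": float((p ** 2).sum()),
        "max_gradient": float(grad[gmax]),
        "max_gradient_intensity_hu": grey.bin_centre(gmax + 1),
        "min_gradient": float(grad[gmin]),
        "min_gradient_intensity_hu": grey.bin_centre(gmin + 1),
    }
    return {k: out[k] for k in HIST_FEATURES}


def intensity_histogram_features(
    hu_values: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()
) -> dict[str, float]:
    """Histogram-family features of a flat HU value array.

    Convenience wrapper: discretises the values with ``spec`` and returns
    the histogram family plus the raw-HU interquartile range under the
    key ``iqr_hu``.
    """
    v = np.asarray(hu_values, dtype=float).ravel()
    if v.size == 0:
        raise EmptyROIError("no values")
    vol = v.reshape(1, 1, -1)
    mask = np.ones_like(vol, dtype=bool)
    grey = discretize(vol, mask, spec)
    out = histogram_features(grey)
    out["iqr_hu"] = intensity_statistics(v)["iqr_hu"]
    return out


# ---------------------------------------------------------------------------
# feature bank / extraction

@dataclass
class FeatureConfig:
    """Which features to extract and how.

    The default bank — GLCM and GLRLM families in both 2-D averaged and
    3-D aggregation, first-order statistics and histogram features —
    contains 123 named features.  Feature values depend on the
    discretisation, which is therefore recorded with every output.
    """

    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    glcm_distance: int = 1
    families: tuple[str, ...] = ("glcm_2D", "glcm_3D", "glrlm_2D", "glrlm_3D",
                                 "stat", "hist")

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for fam in self.families:
            if fam.startswith("glcm"):
                suffix = fam.split("_")[1]
                names += [f"glcm_{f}_{suffix}" for f in GLCM_FEATURES]
            elif fam.startswith("glrlm"):
                suffix = fam.split("_")[1]
                names += [f"glrlm_{f}_{suffix}" for f in GLRLM_FEATURES]
            elif fam == "stat":
                names += [f"stat_{f}_3D" for f in STAT_FEATURES]
            elif fam == "hist":
                names += [f"hist_{f}_3D" for f in HIST_FEATURES]
            else:
                raise ValueError(f"unknown feature family {fam!r}")
        return names


#: The four features the downstream models are anchored on.
MANDATORY_FEATURES = (
    "glcm_info_corr_1_2D",
    "glrlm_norm_grey_level_nonuniformity_2D",
    "stat_iqr_hu_3D",
    "hist_min_gradient_intensity_hu_3D",
)

# GLCM/GLRLM analytic limits used when no texture matrix can be formed
_DEGENERATE = {
    "glcm_info_corr_1": 0.0,
    "glcm_info_corr_2": 0.0,
    "glrlm_norm_grey_level_nonuniformity": 1.0,
    "glrlm_norm_run_length_nonuniformity": 1.0,
}


def compute_feature_vector(volume: np.ndarray, mask: np.ndarray,
                           config: FeatureConfig) -> dict[str, float]:
    """All configured features of one masked volume, in bank order."""
    grey = discretize(volume, mask, config.discretization)
    hu = volume[mask.astype(bool)]
    out: dict[str, float] = {}
    for fam in config.families:
        try:
            if fam.startswith("glcm"):
                suffix = fam.split("_")[1]
                mode = "2d_avg" if suffix == "2D" else "3d"
                vals = glcm_features(glcm(grey, config.glcm_distance, mode))
                out.update({f"glcm_{k}_{suffix}": v for k, v in vals.items()})
            elif fam.startswith("glrlm"):
                suffix = fam.split("_")[1]
                mode = "2d_avg" if suffix == "2D" else "3d"
                vals = glrlm_features(glrlm(grey, mode))
                out.update({f"glrlm_{k}_{suffix}": v for k, v in vals.items()})
            elif fam == "stat":
                out.update({f"stat_{k}_3D": v for k, v in intensity_statistics(hu).items()})
            elif fam == "hist":
                out.update({f"hist_{k}_3D": v for k, v in histogram_features(grey).items()})
        except (UndefinedTextureError, EmptyROIError) as exc:
            warnings.warn(
                f"family {fam}: {exc}; filling degenerate values", stacklevel=2
            )
            suffix = fam.split("_")[1] if "_" in fam else "3D"
            base = "glcm" if fam.startswith("glcm") else "glrlm"
            flist = GLCM_FEATURES if base == "glcm" else GLRLM_FEATURES
            for f in flist:
                key = f"{base}_{f}_{suffix}"
                out[key] = _DEGENERATE.get(f"{base}_{f}", float("nan"))
    return out


def extract_features(series: ImageSeries, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature table rows (patient_id, fraction, feature, value) for one
    patient's series; unusable fractions are skipped with a log entry."""
    config = config or FeatureConfig()
    names = config.feature_names()
    rows = []
    for fx in range(1, series.n_fractions + 1):
        if not series.usable[fx - 1] or not series.masks[fx - 1].any():
            logger.info("patient %s fraction %d skipped (unusable mask)",
                        series.patient_id, fx)
            continue
        vec = compute_feature_vector(series.volumes[fx - 1], series.masks[fx - 1], config)
        for name in names:
            rows.append((series.patient_id, fx, name, vec[name]))
    return pd.DataFrame(rows, columns=["patient_id", "fraction", "feature", "value"])


def extract_cohort_features(series_list: list[ImageSeries],
                            config: FeatureConfig | None = None) -> pd.DataFrame:
    """Concatenated feature table for a list of patient series."""
    config = config or FeatureConfig()
    tables = [extract_features(s, config) for s in series_list]
    return pd.concat(tables, ignore_index=True)
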