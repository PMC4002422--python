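"""The 65-feature speckle-texture parameterization of an ROI.

Five feature families, in fixed registry order:

* local statistics (12): per-voxel local entropy, range and standard
  deviation maps over small 3D neighborhoods; for each map the mean, median,
  entropy and standard deviation of its in-ROI values.  Values are normalized
  by the gray-scale resolution: entropy-type values are divided by the bit
  depth, standard-deviation- and range-type values are scaled so the maximal
  two-point spread maps to ~1 (for 8-bit data, sigma is multiplied by 2/256).
* intensity moments (2): skewness and kurtosis (non-excess) of the in-ROI
  intensity distribution.
* co-occurrence (12): gray-level co-occurrence matrices at an offset of 5
  voxels (about one cell diameter) along each of x, y and z; contrast,
  correlation, energy and homogeneity of each.
* granulometry (21): the in-ROI image is binarized and the size distribution
  of dark connected "particles" histogrammed into 12 geometric bins, then
  coarsened to 6 and to 3 bins; all counts normalized by total particle count.
* directional wavelets (18): per en-face slice, a 3-level undecimated
  separable wavelet transform; detail bands oriented along x, along y and at
  45 degrees; mean and standard deviation of in-ROI coefficient magnitudes
  per direction and scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy import stats as sstats
from skimage.filters import threshold_otsu

from .types import ImageStack, RoiMask, ValidationError

__all__ = [
    "FEATURE_REGISTRY",
    "FEATURE_GROUPS",
    "FeatureConfig",
    "FeatureVector",
    "feature_matrix",
    "local_stat_features",
    "moment_features",
    "cooccurrence_features",
    "granulometry_features",
    "wavelet_features",
    "extract_features",
]

# ---------------------------------------------------------------- registry

_LOCAL_MAPS = ("entropy", "range", "std")
_LOCAL_STATS = ("mean", "median", "entropy", "std")
_COOC_AXES = ("x", "y", "z")
_COOC_STATS = ("contrast", "correlation", "energy", "homogeneity")
_WAVE_DIRS = ("x", "y", "diag45")

FEATURE_GROUPS: Dict[str, List[str]] = {
    "local_stats": [f"local_{m}_{s}" for m in _LOCAL_MAPS for s in _LOCAL_STATS],
    "moments": ["intensity_skewness", "intensity_kurtosis"],
    "cooccurrence": [f"glcm_{a}_{s}" for a in _COOC_AXES for s in _COOC_STATS],
    "granulometry": (
        [f"granulo12_bin{i}" for i in range(12)]
        + [f"granulo6_bin{i}" for i in range(6)]
        + [f"granulo3_bin{i}" for i in range(3)]
    ),
    "wavelet": [
        f"dwt_{d}_scale{s}_{st}" for d in _WAVE_DIRS for s in (1, 2, 3) for st in ("mean", "std")
    ],
}

FEATURE_REGISTRY: List[str] = [n for names in FEATURE_GROUPS.values() for n in names]

_expected = {"local_stats": 12, "moments": 2, "cooccurrence": 12, "granulometry": 21, "wavelet": 18}
for _g, _n in _expected.items():
    assert len(FEATURE_GROUPS[_g]) == _n, (_g, len(FEATURE_GROUPS[_g]))
assert len(FEATURE_REGISTRY) == 65


@dataclass
class FeatureConfig:
    """Tunable knobs of the parameterization (defaults follow the registry docs)."""

    entropy_window: int = 5  # cubic neighborhood edge for the local entropy map
    entropy_levels: int = 32  # gray bins for the local entropy estimate
    range_window: int = 3
    std_window: int = 3
    cooc_offset_vox: int = 5
    cooc_levels: int = 8
    granulo_bin_edges: Optional[Sequence[float]] = None  # default: 2**0 .. 2**12
    wavelet_name: str = "bior2.2"
    wavelet_scales: int = 3

    def granulo_edges(self) -> np.ndarray:
        if self.granulo_bin_edges is not None:
            edges = np.asarray(self.granulo_bin_edges, dtype=float)
            if edges.size != 13 or np.any(np.diff(edges) <= 0):
                raise ValidationError("granulo_bin_edges must be 13 increasing bounds")
            return edges
        return 2.0 ** np.arange(13)  # 1, 2, 4, ..., 4096 voxels


@dataclass
class FeatureVector:
    values: np.ndarray  # 65 floats, registry order
    names: Tuple[str, ...] = tuple(FEATURE_REGISTRY)
    bit_depth_used: int = 8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (65,):
            raise ValidationError(f"feature vector must have 65 entries, got {v.shape}")
        if not np.all(np.isfinite(v)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(v))]
            raise ValidationError(f"non-finite features: {bad}")
        self.values = v

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def feature_matrix(
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    subset_ids: Sequence[str],
    timepoints: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Tidy frame: one row per ROI, canonical feature columns + bookkeeping."""
    if not (len(vectors) == len(labels) == len(subset_ids)):
        raise ValidationError("vectors, labels and subset_ids must align")
    df = pd.DataFrame([fv.values for fv in vectors], columns=FEATURE_REGISTRY)
    df["label"] = list(labels)
    df["subset_id"] = [str(s) for s in subset_ids]
    if timepoints is not None:
        df["timepoint"] = list(timepoints)
    return df


# ---------------------------------------------------------------- local stats


def _local_entropy_map(v: np.ndarray, window: int, levels: int, vmax: int) -> np.ndarray:
    """Shannon entropy (bits) of the local gray histogram in a cubic window.

    Computed as a sum over gray bins of uniform-filtered bin indicators —
    exact, separable and fast for a modest number of bins.
    """
    q = np.minimum((v.astype(np.int64) * levels) // (vmax + 1), levels - 1)
    size = (window,) * 3
    ent = np.zeros(v.shape, dtype=float)
    for b in np.unique(q):
        p = ndimage.uniform_filter((q == b).astype(float), size=size, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log2(p), 0.0)
        ent += term
    return ent


def _map_summary(map_vals: np.ndarray, bit_depth: int) -> List[float]:
    """mean, median, entropy, std of one local map's in-ROI values.

    ``map_vals`` are already normalized to [0, 1]; the map-entropy is the
    Shannon entropy of their histogram over 2**bit_depth bins, normalized by
    bit_depth so that a flat histogram scores 1.
    """
    nbins = 1 << bit_depth
    hist, _ = np.histogram(map_vals, bins=nbins, range=(0.0, 1.0 + 1e-12))
    p = hist[hist > 0] / hist.sum()
    ent = float(-(p * np.log2(p)).sum()) / bit_depth
    return [float(np.mean(map_vals)), float(np.median(map_vals)), ent, float(np.std(map_vals))]


def local_stat_features(
    stack: ImageStack, roi: RoiMask, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    w = max(config.entropy_window, config.range_window, config.std_window)
    if min(stack.shape) < w:
        raise ValidationError(f"ROI stack smaller than the {w}-voxel neighborhood")
    v = stack.voxels.astype(float)
    vmax = stack.max_level
    ent = _local_entropy_map(stack.voxels, config.entropy_window, config.entropy_levels, vmax)
    ent_n = ent / stack.bit_depth
    size_r = (config.range_window,) * 3
    rng_map = ndimage.maximum_filter(v, size=size_r, mode="nearest") - ndimage.minimum_filter(
        v, size=size_r, mode="nearest"
    )
    rng_n = rng_map / vmax
    size_s = (config.std_window,) * 3
    mu = ndimage.uniform_filter(v, size=size_s, mode="nearest")
    mu2 = ndimage.uniform_filter(v * v, size=size_s, mode="nearest")
    std_map = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
    std_n = std_map * 2.0 / (1 << stack.bit_depth)
    out: List[float] = []
    m = roi.mask
    for nm in (ent_n, rng_n, std_n):
        out.extend(_map_summary(nm[m], stack.bit_depth))
    return np.asarray(out)


# ---------------------------------------------------------------- moments


def moment_features(stack: ImageStack, roi: RoiMask) -> np.ndarray:
    vals = stack.voxels[roi.mask].astype(float)
    if np.var(vals) == 0:
        warnings.warn("zero in-ROI variance; moments set to (0, 0) by convention")
        return np.array([0.0, 0.0])
    skew = float(sstats.skew(vals, bias=True))
    kurt = float(sstats.kurtosis(vals, fisher=False, bias=True))
    return np.array([skew, kurt])


# ---------------------------------------------------------------- co-occurrence


def _glcm_stats(P: np.ndarray) -> List[float]:
    """contrast, correlation, energy, homogeneity of one normalized GLCM."""
    levels = P.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((P * (ii - jj) ** 2).sum())
    energy = float((P * P).sum())
    homog = float((P / (1.0 + np.abs(ii - jj))).sum())
    pi = P.sum(axis=1)
    mu_i = float((i * pi).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    if var_i <= 0:
        corr = 1.0  # degenerate single-level matrix
    else:
        corr = float((P * (ii - mu_i) * (jj - mu_i)).sum() / var_i)  # symmetric GLCM
    return [contrast, corr, energy, homog]


def cooccurrence_features(
    stack: ImageStack,
    roi: RoiMask,
    offset_vox: int = 5,
    levels: int = 8,
) -> np.ndarray:
    v = stack.voxels
    vmax = stack.max_level
    q = np.minimum((v.astype(np.int64) * levels) // (vmax + 1), levels - 1)
    m = roi.mask
    out: List[float] = []
    # axis order in the registry is x, y, z -> array axes 2, 1, 0
    for name, ax in (("x", 2), ("y", 1), ("z", 0)):
        if stack.shape[ax] <= offset_vox:
            raise ValidationError(f"ROI extent along {name} does not exceed offset {offset_vox}")
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, stack.shape[ax] - offset_vox)
        sl_b[ax] = slice(offset_vox, None)
        pair_ok = m[tuple(sl_a)] & m[tuple(sl_b)]
        a = q[tuple(sl_a)][pair_ok]
        b = q[tuple(sl_b)][pair_ok]
        if a.size == 0:
            raise ValidationError(f"no valid in-ROI voxel pairs along {name}")
        C = np.zeros((levels, levels), dtype=np.int64)
        np.add.at(C, (a, b), 1)
        C = C + C.T  # symmetrize
        P = C / C.sum()
        out.extend(_glcm_stats(P))
    return np.asarray(out)


# ---------------------------------------------------------------- granulometry


def granulometry_features(
    stack: ImageStack,
    roi: RoiMask,
    bin_edges_12: Optional[Sequence[float]] = None,
) -> np.ndarray:
    edges = FeatureConfig(granulo_bin_edges=bin_edges_12).granulo_edges()
    vals = stack.voxels[roi.mask]
    m = roi.mask
    if vals.min() == vals.max():
        black = np.zeros(stack.shape, dtype=bool)  # constant ROI: no particles
    else:
        thr = threshold_otsu(vals.ravel())
        black = (stack.voxels <= thr) & m
    lab, n = ndimage.label(black, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return np.zeros(21)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    sizes = np.clip(sizes, edges[0], edges[-1])  # oversize particles fall in the last bin
    # np.histogram's last bin is closed on the right, so clipped sizes land there
    h12, _ = np.histogram(sizes, bins=edges)
    h12 = h12.astype(float)
    total = h12.sum()
    h12 /= total
    h6 = h12.reshape(6, 2).sum(axis=1)
    h3 = h6.reshape(3, 2).sum(axis=1)
    return np.concatenate([h12, h6, h3])


# ---------------------------------------------------------------- wavelets


def _swt_details(img: np.ndarray, wavelet: str, n_scales: int) -> List[Dict[str, np.ndarray]]:
    """Undecimated 2D wavelet detail bands, finest scale first.

    Returns per-scale dicts with keys 'x' (detail along x), 'y' (detail along
    y) and 'diag45', each the same shape as ``img`` so ROI masking is exact.
    """
    ny, nx = img.shape
    mult = 1 << n_scales
    py = (-ny) % mult
    px = (-nx) % mult
    padded = np.pad(img, ((0, py), (0, px)), mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=n_scales, axes=(0, 1))
    # pywt.swtn returns coarsest level first; reverse so index 0 = finest scale
    out = []
    for level in reversed(coeffs):
        out.append(
            {
                "x": np.abs(level["ad"][:ny, :nx]),  # approx along y, detail along x
                "y": np.abs(level["da"][:ny, :nx]),
                "diag45": np.abs(level["dd"][:ny, :nx]),
            }
        )
    return out


def wavelet_features(
    stack: ImageStack,
    roi: RoiMask,
    n_scales: int = 3,
    wavelet: str = "bior2.2",
) -> np.ndarray:
    nz, ny, nx = stack.shape
    if min(ny, nx) < (1 << n_scales):
        raise ValidationError(f"in-plane extent must be >= 2^{n_scales}")
    v = stack.voxels.astype(float) / stack.max_level
    pooled: Dict[Tuple[str, int], List[np.ndarray]] = {
        (d, s): [] for d in _WAVE_DIRS for s in range(n_scales)
    }
    for z in range(nz):
        mz = roi.mask[z]
        if not mz.any():
            continue
        bands = _swt_details(v[z], wavelet, n_scales)
        for s, level in enumerate(bands):
            for d in _WAVE_DIRS:
                pooled[(d, s)].append(level[d][mz])
    out: List[float] = []
    for d in _WAVE_DIRS:
        for s in range(n_scales):
            chunks = pooled[(d, s)]
            if not chunks:
                raise ValidationError("ROI intersects no en-face slice")
            allv = np.concatenate(chunks)
            out.extend([float(allv.mean()), float(allv.std())])
    return np.asarray(out)


# ---------------------------------------------------------------- assembly


def extract_features(
    stack: ImageStack,
    roi: RoiMask,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Concatenate all five families in registry order (65 values)."""
    parts = [
        local_stat_features(stack, roi, config),
        moment_features(stack, roi),
        cooccurrence_features(stack, roi, config.cooc_offset_vox, config.cooc_levels),
        granulometry_features(stack, roi, config.granulo_bin_edges),
        wavelet_features(stack, roi, config.wavelet_scales, config.wavelet_name),
    ]
    return FeatureVector(values=np.concatenate(parts), bit_depth_used=stack.bit_depth)
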