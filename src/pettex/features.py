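"""Conventional SUV metrics and 3-D texture features on a tumor VOI.

Nine PET parameters per lesion:

* conventional, on floating-point SUV data: SUVmax, SUVmean, metabolic tumor
  volume (MTV, ml) and coefficient of variation (COV = population SD / mean);
* textural, on VOI SUVs rescaled to 64 gray levels by

      R(x) = 64 * (I(x) - SUVmin) / (SUVmax - SUVmin)

  with bin(x) = clamp(floor(R(x)) + 1, 1, 64): gray-level co-occurrence
  matrix (GLCM) entropy, correlation and contrast, pooled over the 13 unique
  3-D unit offsets, and neighborhood gray-tone difference matrix (NGTDM)
  coarseness and busyness in the Amadasun-King form over the 26-neighborhood.

The co-occurrence offset length is fixed at one voxel in index space; the
grid's anisotropy (4.06 mm in-plane vs 5.0 mm axial by default) is ignored
when forming offsets, which is a known bias of pure matrix methods.
NGTDM neighborhoods are restricted to in-mask voxels — the VOI boundary is a
tissue boundary, not an image border, so it contributes no gray tones.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import VOIMask, segment_isocontour
from .volume import PETVolume

#: Coarseness regularizer; a perfectly flat VOI reports the cap 1/EPS_COARSENESS.
EPS_COARSENESS = 1e-6

#: The 13 unique 3-D unit offsets: one representative per +/- direction pair.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
)
assert len(OFFSETS_13) == 13

#: Full 26-neighborhood for NGTDM.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


class FeatureError(ValueError):
    """Raised on degenerate inputs for which a feature is undefined."""


# ---------------------------------------------------------------------------
# conventional SUV statistics


@dataclass
class SUVStats:
    suv_max: float
    suv_mean: float
    mtv_ml: float
    cov: float


def suv_statistics(volume: PETVolume, mask: VOIMask) -> SUVStats:
    """SUVmax, SUVmean, MTV (ml) and COV over the VOI, on floating-point SUV.

    COV uses the population standard deviation (ddof=0).
    """
    if mask.mask.shape != volume.suv.shape:
        raise FeatureError("mask and volume shapes differ")
    vals = volume.suv[mask.mask]
    if vals.size == 0:
        raise FeatureError("empty VOI")
    mean = float(vals.mean())
    if mean == 0:
        raise FeatureError("COV undefined: mean SUV in VOI is zero")
    return SUVStats(
        suv_max=float(vals.max()),
        suv_mean=mean,
        mtv_ml=vals.size * volume.voxel_volume_mm3 / 1000.0,
        cov=float(vals.std(ddof=0)) / mean,
    )


# ---------------------------------------------------------------------------
# discretization


@dataclass
class DiscretizedVolume:
    """VOI SUVs resampled to integer gray levels 1..n_bins.

    ``bins`` is a full-grid integer array, 0 outside the VOI.  A flat VOI
    (suv_min == suv_max) maps every voxel to bin 1.
    """

    bins: np.ndarray
    n_bins: int
    suv_min: float
    suv_max: float


def discretize_suv(volume: PETVolume, mask: VOIMask, n_bins: int = 64
                   ) -> DiscretizedVolume:
    """Rescale VOI SUVs to ``n_bins`` gray levels.

    R(x) = n_bins * (I(x) - SUVmin) / (SUVmax - SUVmin) over VOI voxels,
    then bin(x) = clamp(floor(R(x)) + 1, 1, n_bins), so the VOI minimum falls
    in bin 1 and the maximum in bin ``n_bins``.
    """
    if mask.mask.shape != volume.suv.shape:
        raise FeatureError("mask and volume shapes differ")
    vals = volume.suv[mask.mask]
    if vals.size == 0:
        raise FeatureError("empty VOI")
    lo, hi = float(vals.min()), float(vals.max())
    bins = np.zeros(volume.suv.shape, dtype=np.int64)
    if hi == lo:
        bins[mask.mask] = 1
    else:
        r = n_bins * (vals - lo) / (hi - lo)
        bins[mask.mask] = np.clip(np.floor(r).astype(np.int64) + 1, 1, n_bins)
    return DiscretizedVolume(bins=bins, n_bins=int(n_bins), suv_min=lo, suv_max=hi)


# ---------------------------------------------------------------------------
# GLCM


@dataclass
class GLCMatrix:
    """Symmetric joint gray-level co-occurrence probabilities (sum 1)."""

    p: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    aggregation: Literal["merged", "averaged"]


def _offset_pairs(bins: np.ndarray, mask: np.ndarray,
                  offset: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Gray levels of ordered in-mask voxel pairs separated by `offset`."""
    src = [slice(max(-d, 0), bins.shape[a] - max(d, 0)) for a, d in enumerate(offset)]
    dst = [slice(max(d, 0), bins.shape[a] + min(d, 0)) for a, d in enumerate(offset)]
    valid = mask[tuple(src)] & mask[tuple(dst)]
    return bins[tuple(src)][valid], bins[tuple(dst)][valid]


def compute_glcm(disc: DiscretizedVolume, mask: VOIMask,
                 aggregation: Literal["merged", "averaged"] = "merged",
                 offsets: Sequence[tuple[int, int, int]] = OFFSETS_13
                 ) -> GLCMatrix:
    """Symmetrized 3-D GLCM over the given unit offsets.

    For each offset, ordered co-occurrences between in-mask voxel pairs are
    counted and symmetrized by adding the transpose.  ``merged`` pools counts
    across all offsets before normalizing to a probability matrix;
    ``averaged`` normalizes each offset's matrix separately and averages the
    matrices of offsets that produced at least one pair.
    """
    n = disc.n_bins
    per_offset = []
    for off in offsets:
        a, b = _offset_pairs(disc.bins, mask.mask, off)
        counts = np.zeros((n, n), dtype=np.float64)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
            counts += counts.T.copy()
        per_offset.append(counts)
    totals = [c.sum() for c in per_offset]
    if sum(totals) == 0:
        raise FeatureError("no co-occurrences: VOI has no in-mask neighbor pairs")
    if aggregation == "merged":
        pooled = np.sum(per_offset, axis=0)
        p = pooled / pooled.sum()
    elif aggregation == "averaged":
        mats = [c / t for c, t in zip(per_offset, totals) if t > 0]
        p = np.mean(mats, axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return GLCMatrix(p=p, offsets=tuple(offsets), aggregation=aggregation)


@dataclass
class GLCMFeatures:
    entropy: float
    correlation: float
    contrast: float
    entropy_log_base: float


def glcm_features(g: GLCMatrix, entropy_base: float = 2.0) -> GLCMFeatures:
    """Joint entropy, correlation and contrast of a co-occurrence matrix.

    entropy  = -sum p(i,j) log_b p(i,j)        (bits for b = 2)
    contrast =  sum (i - j)^2 p(i,j)
    correlation = sum (i - mu)(j - mu) p(i,j) / sigma^2, with mu and sigma
    the marginal mean and SD (the two marginals coincide by symmetry).
    A single-gray-level VOI has sigma = 0; correlation is then defined as 1
    (perfect degenerate dependence) and a warning is emitted.
    """
    p = g.p
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise FeatureError("GLCM is not a probability matrix")
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(entropy_base))).sum())
    levels = np.arange(1, p.shape[0] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    contrast = float(((ii - jj) ** 2 * p).sum())
    marg = p.sum(axis=1)
    mu = float((levels * marg).sum())
    var = float(((levels - mu) ** 2 * marg).sum())
    if var == 0:
        warnings.warn("GLCM has a single occupied gray level; correlation := 1",
                      RuntimeWarning, stacklevel=2)
        corr = 1.0
    else:
        corr = float((((ii - mu) * (jj - mu)) * p).sum() / var)
    return GLCMFeatures(entropy=entropy, correlation=corr, contrast=contrast,
                        entropy_log_base=float(entropy_base))


# ---------------------------------------------------------------------------
# NGTDM


@dataclass
class NGTDMTable:
    """Per-gray-level occupancy p_i and total deviation s_i from the local
    neighborhood mean, over voxels that have at least one in-mask neighbor."""

    levels: np.ndarray
    p: np.ndarray
    s: np.ndarray


def compute_ngtdm(disc: DiscretizedVolume, mask: VOIMask) -> NGTDMTable:
    """Neighborhood gray-tone difference table over the 26-neighborhood.

    For each VOI voxel with >= 1 in-mask neighbor, the neighborhood average
    gray tone A is the mean bin of its in-mask 26-neighbors (the voxel itself
    excluded); s_i accumulates |i - A| over voxels of level i and p_i is the
    fraction of valid voxels at level i.
    """
    m = mask.mask
    bins = disc.bins
    nbr_sum = np.zeros(bins.shape, dtype=np.float64)
    nbr_cnt = np.zeros(bins.shape, dtype=np.float64)
    for off in OFFSETS_26:
        src = [slice(max(-d, 0), bins.shape[a] - max(d, 0)) for a, d in enumerate(off)]
        dst = [slice(max(d, 0), bins.shape[a] + min(d, 0)) for a, d in enumerate(off)]
        nbr_sum[tuple(dst)] += np.where(m[tuple(src)], bins[tuple(src)], 0)
        nbr_cnt[tuple(dst)] += m[tuple(src)]
    valid = m & (nbr_cnt > 0)
    if not valid.any():
        raise FeatureError("NGTDM undefined: no VOI voxel has an in-mask neighbor")
    lv = bins[valid].astype(np.float64)
    dev = np.abs(lv - nbr_sum[valid] / nbr_cnt[valid])
    levels = np.unique(bins[valid])
    p = np.array([(bins[valid] == i).sum() for i in levels], dtype=np.float64)
    p /= p.sum()
    s = np.array([dev[bins[valid] == i].sum() for i in levels], dtype=np.float64)
    return NGTDMTable(levels=levels.astype(np.int64), p=p, s=s)


def ngtdm_features(t: NGTDMTable, eps: float = EPS_COARSENESS
                   ) -> tuple[float, float]:
    """Amadasun-King coarseness and busyness.

    coarseness = 1 / (eps + sum_i p_i s_i), capped at 1/eps for a flat VOI;
    busyness   = sum_i p_i s_i / sum_{i != j} |i p_i - j p_j| over occupied
    level pairs, defined as 0 when only one gray level is occupied.
    """
    if t.p.size == 0:
        raise FeatureError("empty NGTDM table")
    ps = float((t.p * t.s).sum())
    coarseness = 1.0 / (eps + ps)
    lv = t.levels.astype(np.float64)
    ip = lv * t.p
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())  # i == j terms are 0
    busyness = ps / denom if denom > 0 else 0.0
    return coarseness, busyness


# ---------------------------------------------------------------------------
# full per-lesion feature vector


@dataclass
class FeatureVector:
    """The nine PET parameters of one lesion, plus provenance fields."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    cov: float
    entropy: float
    correlation: float
    contrast: float
    coarseness: float
    busyness: float
    voi_threshold: float
    n_voxels: int
    entropy_log_base: float = 2.0
    diameter_mm: Optional[float] = None
    patient_id: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


#: Columns holding the nine analysed PET parameters, in reporting order.
PARAMETER_COLUMNS = ("suv_max", "suv_mean", "mtv_ml", "cov", "entropy",
                     "correlation", "contrast", "coarseness", "busyness")


def extract_all_features(volume: PETVolume,
                         threshold_suv: float = 2.0,
                         connectivity: int = 26,
                         n_bins: int = 64,
                         aggregation: Literal["merged", "averaged"] = "merged",
                         entropy_base: float = 2.0,
                         mask: Optional[VOIMask] = None,
                         diameter_mm: Optional[float] = None) -> FeatureVector:
    """Segment a lesion and compute all nine PET parameters.

    A precomputed ``mask`` may be supplied in place of automatic isocontour
    segmentation (the hook for externally corrected VOIs).
    """
    if mask is None:
        mask = segment_isocontour(volume, threshold_suv, connectivity)
    stats = suv_statistics(volume, mask)
    disc = discretize_suv(volume, mask, n_bins=n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # flat-VOI correlation
        if mask.n_voxels > 1:
            glcm = compute_glcm(disc, mask, aggregation=aggregation)
            gf = glcm_features(glcm, entropy_base=entropy_base)
            coarseness, busyness = ngtdm_features(compute_ngtdm(disc, mask))
        else:
            # single-voxel lesion: no pairs, no neighborhoods
            gf = GLCMFeatures(0.0, 1.0, 0.0, entropy_base)
            coarseness, busyness = 1.0 / EPS_COARSENESS, 0.0
    return FeatureVector(
        suv_max=stats.suv_max, suv_mean=stats.suv_mean, mtv_ml=stats.mtv_ml,
        cov=stats.cov, entropy=gf.entropy, correlation=gf.correlation,
        contrast=gf.contrast, coarseness=coarseness, busyness=busyness,
        voi_threshold=mask.threshold_suv, n_voxels=mask.n_voxels,
        entropy_log_base=entropy_base, diameter_mm=diameter_mm,
        patient_id=volume.patient_id)


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack per-lesion feature vectors into a table, one row per lesion."""
    return pd.DataFrame([f.to_dict() for f in features])
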