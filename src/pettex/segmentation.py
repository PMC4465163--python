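"""Tumor volume-of-interest (VOI) definition by SUV isocontour.

The VOI is the connected component of supra-threshold voxels that contains
the hottest voxel: a 3-D SUV isocontour around the uptake maximum, the
standard fixed-threshold delineation for FDG-avid lung lesions (SUV 2.0 by
default, SUV 2.5 as the alternative used for stability analysis).

The threshold comparison is closed (``SUV >= threshold``) and connectivity
defaults to the 26-neighborhood; both are configurable because either choice
can change component membership on real data.  Coordinates are 0-based voxel
indices; physical quantities enter only through the volume's spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .volume import PETVolume

#: skimage `connectivity` argument (neighbors sharing a face/edge/vertex)
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class SegmentationError(ValueError):
    """Raised when no valid VOI can be formed."""


@dataclass
class VOIMask:
    """A segmented tumor region tied to the SUV threshold that produced it."""

    mask: np.ndarray
    threshold_suv: float
    connectivity: int
    seed_voxel: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise SegmentationError("connectivity must be 6, 18 or 26")
        if not self.mask.any():
            raise SegmentationError("VOI mask is empty")
        if not self.mask[tuple(self.seed_voxel)]:
            raise SegmentationError("seed voxel is not inside the VOI mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_ml(self, volume: PETVolume) -> float:
        """Metabolic tumor volume in ml (voxel count x voxel volume)."""
        return self.n_voxels * volume.voxel_volume_mm3 / 1000.0


def hottest_voxel(volume: PETVolume,
                  search_box: Optional[tuple[tuple[int, int, int],
                                             tuple[int, int, int]]] = None
                  ) -> tuple[int, int, int]:
    """Coordinates of the maximum-SUV voxel; ties go to the lexicographically
    smallest coordinate.

    Parameters
    ----------
    search_box : ((z0, y0, x0), (z1, y1, x1)), optional
        Half-open bounds restricting the search; whole grid if omitted.
    """
    suv = volume.suv
    if search_box is None:
        lo = (0, 0, 0)
        sub = suv
    else:
        lo, hi = search_box
        lo = tuple(int(v) for v in lo)
        hi = tuple(int(v) for v in hi)
        if any(l < 0 or h > s or l >= h
               for l, h, s in zip(lo, hi, suv.shape)):
            raise SegmentationError(f"empty or out-of-bounds search box {search_box}")
        sub = suv[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    # C-order argmax on the first occurrence == lexicographic tie-break
    flat = int(np.argmax(sub))
    idx = np.unravel_index(flat, sub.shape)
    return tuple(int(i + o) for i, o in zip(idx, lo))


def segment_isocontour(volume: PETVolume,
                       threshold_suv: float = 2.0,
                       connectivity: int = 26,
                       seed: Optional[tuple[int, int, int]] = None) -> VOIMask:
    """Segment the SUV isocontour VOI around a seed voxel.

    The mask is the connected component (under `connectivity`) of
    ``{x : SUV(x) >= threshold_suv}`` containing the seed, which defaults to
    the hottest voxel of the whole grid.

    Raises
    ------
    SegmentationError
        If the seed voxel itself lies below the threshold — clinically, no
        FDG-avid lesion exists at this isocontour level.
    """
    if threshold_suv <= 0:
        raise SegmentationError("threshold_suv must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise SegmentationError("connectivity must be 6, 18 or 26")
    if seed is None:
        seed = hottest_voxel(volume)
    seed = tuple(int(v) for v in seed)
    supra = volume.suv >= threshold_suv
    if not supra[seed]:
        raise SegmentationError(
            f"no lesion at threshold: seed voxel {seed} has "
            f"SUV {volume.suv[seed]:.3g} < {threshold_suv:g}")
    labels = measure.label(supra, connectivity=_CONNECTIVITY_RANK[connectivity])
    mask = labels == labels[seed]
    return VOIMask(mask=mask, threshold_suv=float(threshold_suv),
                   connectivity=connectivity, seed_voxel=seed)


def write_mask_nifti(mask: VOIMask, volume: PETVolume, path) -> None:
    """Write a VOI mask as a uint8 NIfTI sharing the volume's geometry."""
    import nibabel as nib
    import numpy as _np

    if mask.mask.shape != volume.suv.shape:
        raise SegmentationError("mask and volume shapes differ")
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.mask.astype(_np.uint8), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask_nifti(path, volume: PETVolume, threshold_suv: float,
                    connectivity: int = 26) -> VOIMask:
    """Read a binary VOI mask (e.g. an externally corrected one) and bind it
    to its volume; the seed voxel is the hottest masked voxel."""
    import nibabel as nib

    arr = np.asarray(nib.load(str(path)).get_fdata()) > 0.5
    if arr.shape != volume.suv.shape:
        raise SegmentationError("mask file geometry does not match the volume")
    if not arr.any():
        raise SegmentationError("mask file is empty")
    masked = np.where(arr, volume.suv, -np.inf)
    seed = tuple(int(i) for i in
                 np.unravel_index(int(np.argmax(masked)), arr.shape))
    return VOIMask(mask=arr, threshold_suv=float(threshold_suv),
                   connectivity=connectivity, seed_voxel=seed)
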