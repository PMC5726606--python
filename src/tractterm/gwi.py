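"""Grey–white interface (GWI) seed extraction and the tracking exclusion mask.

Seeds are the white-matter voxels on the external surface of the WM mask —
those with at least one face-adjacent (6-neighbourhood by default) voxel
outside the mask — intersected with a lobe mask that restricts the analysis
to the cortical region of interest.  Everything outside the white matter is
the exclusion mask that stops streamlines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid


@dataclass(frozen=True)
class SeedSet:
    """GWI seed voxels (0-based integer index triples) within the lobe mask."""

    indices: np.ndarray  # (n, 3) int64
    count: int

    def as_mask(self, grid: VolumeGrid) -> np.ndarray:
        mask = np.zeros(grid.shape, dtype=bool)
        if self.count:
            mask[tuple(self.indices.T)] = True
        return mask


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def surface_mask(wm_mask: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """External-surface voxels of a binary mask.

    A voxel is on the surface if any of its neighbours (under the given
    connectivity) is outside the mask; neighbours beyond the grid bounds count
    as outside.
    """
    wm = np.asarray(wm_mask, dtype=bool)
    interior = ndimage.binary_erosion(wm, structure=_structure(connectivity),
                                      border_value=0)
    return wm & ~interior


def extract_gwi(wm_mask: np.ndarray, lobe_mask: np.ndarray,
                connectivity: int = 6) -> SeedSet:
    """Extract GWI seed voxels: WM surface voxels that fall in the lobe mask."""
    wm = np.asarray(wm_mask, dtype=bool)
    lobe = np.asarray(lobe_mask, dtype=bool)
    if wm.shape != lobe.shape:
        raise ValueError(
            f"wm_mask shape {wm.shape} != lobe_mask shape {lobe.shape}")
    if not wm.any():
        warnings.warn("empty white-matter mask: no GWI seeds", stacklevel=2)
        return SeedSet(indices=np.empty((0, 3), dtype=np.int64), count=0)
    seeds = surface_mask(wm, connectivity=connectivity) & lobe
    idx = np.argwhere(seeds).astype(np.int64)
    return SeedSet(indices=idx, count=int(idx.shape[0]))


def build_exclusion_mask(wm_mask: np.ndarray) -> np.ndarray:
    """Tracking exclusion mask: every voxel outside the white matter."""
    return ~np.asarray(wm_mask, dtype=bool)
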