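"""Raw termination maps: per-seed tract contribution proportions.

For each tract, a subject's termination map assigns to every GWI seed voxel
the proportion of that seed's streamlines that reached the tract's selection
ROI (e.g. 1000 of 10,000 streamlines gives intensity 0.1).  Subject maps are
Gaussian-smoothed (5 mm FWHM by default, to absorb gyrification differences),
averaged across the cohort, and finally rescaled to [0, 1] so that the map
maximum marks the most probable termination site.  Smoothing and rescaling
are display transforms for the raw group maps; the pairwise statistics
consume the un-rescaled, unsmoothed subject maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VolumeGrid
from .gwi import SeedSet
from .phantom import Phantom
from .tracking import propagate_streamlines, seed_rng, Streamline, TrackingParams

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TractROI:
    """Binary mask in the body of a tract, used to select its streamlines."""

    name: str
    mask: np.ndarray
    centroid_mm: tuple[float, float, float] | None = None
    plane: str | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"tract ROI {self.name!r} is empty")
        _, n_comp = ndimage.label(self.mask)
        if n_comp > 1:
            warnings.warn(
                f"tract ROI {self.name!r} has {n_comp} connected components",
                stacklevel=2)


@dataclass
class TerminationMap:
    """One tract × subject termination map.

    ``proportions`` holds contribution proportions in [0, 1]; ``counts`` the
    un-normalised streamline counts, kept for the statistics stage.
    """

    tract: str
    subject: int
    proportions: np.ndarray
    counts: np.ndarray
    n_streamlines: int
    smoothed: bool = False
    rescaled: bool = False


def streamline_hits_roi(streamline: Streamline | np.ndarray, roi: TractROI,
                        grid: VolumeGrid) -> bool:
    """True iff any point of the streamline falls in an ROI voxel."""
    pts = streamline.points if isinstance(streamline, Streamline) else streamline
    vox = grid.world_to_voxel(np.asarray(pts, dtype=float))
    ok = grid.inside(vox)
    if not ok.any():
        return False
    v = vox[ok]
    return bool(roi.mask[v[:, 0], v[:, 1], v[:, 2]].any())


def raw_termination_value(seed_streamlines, roi: TractROI,
                          n_streamlines: int, grid: VolumeGrid) -> float:
    """Proportion of a seed's streamlines that contribute to the tract."""
    if n_streamlines <= 0:
        raise ValueError("n_streamlines must be positive")
    hits = sum(streamline_hits_roi(s, roi, grid) for s in seed_streamlines)
    return hits / n_streamlines


def subject_termination_maps(phantom: Phantom, seeds: SeedSet,
                             rois: list[TractROI], params: TrackingParams,
                             subject: int = 0,
                             global_counts: np.ndarray | None = None
                             ) -> dict[str, TerminationMap]:
    """Track every seed of one subject and build its raw termination maps.

    Each seed launches ``params.n_streamlines`` streamlines (RNG split
    hierarchically per subject and seed voxel); the count of streamlines
    hitting each tract ROI is assigned to the seed's voxel.  If
    ``global_counts`` is given, per-seed visitation counts are accumulated
    into it, yielding the subject's global connectivity profile.
    """
    grid = phantom.grid
    roi_masks = tuple(r.mask for r in rois)
    count_vols = {r.name: grid.zeros(dtype=np.int64) for r in rois}
    shape = grid.shape
    record_visits = global_counts is not None
    for ijk in seeds.indices:
        flat = int(np.ravel_multi_index(tuple(ijk), shape))
        rng = seed_rng(params, subject, flat)
        centre = grid.voxel_to_world(np.asarray(ijk, dtype=float))
        starts = np.tile(centre, (params.n_streamlines, 1))
        res = propagate_streamlines(starts, phantom, params, rng,
                                    roi_masks=roi_masks,
                                    record_visits=record_visits)
        if record_visits:
            flat_counts = np.bincount(res.visit_voxels,
                                      minlength=global_counts.size)
            global_counts += flat_counts.reshape(shape).astype(global_counts.dtype)
        n_hits = res.roi_hits.sum(axis=0)
        for r, h in zip(rois, n_hits):
            count_vols[r.name][tuple(ijk)] = int(h)
    return {
        name: TerminationMap(
            tract=name, subject=subject, counts=counts,
            proportions=counts / params.n_streamlines,
            n_streamlines=params.n_streamlines)
        for name, counts in count_vols.items()
    }


def smooth_map(volume: np.ndarray, grid: VolumeGrid,
               fwhm_mm: float = 5.0) -> np.ndarray:
    """Gaussian smoothing with the given FWHM in mm (zero boundary handling,
    no mask renormalisation); FWHM 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)


def group_map(subject_maps) -> np.ndarray:
    """Voxelwise mean of (smoothed) subject maps."""
    vols = [np.asarray(m.proportions if isinstance(m, TerminationMap) else m,
                       dtype=float) for m in subject_maps]
    if not vols:
        raise ValueError("need at least one subject map")
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError(f"subject map grids differ: {v.shape} vs {shape}")
    return np.mean(vols, axis=0)


def rescale_unit(volume: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant map becomes all zeros (warned)."""
    vol = np.asarray(volume, dtype=float)
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax == vmin:
        warnings.warn("constant map: rescaled to all zeros", stacklevel=2)
        return np.zeros_like(vol)
    return (vol - vmin) / (vmax - vmin)


def load_mni_centroids() -> pd.DataFrame:
    """Tract-ROI centroid coordinates in MNI space (for real-data use),
    columns: tract, hemisphere, x, y, z."""
    from importlib.resources import files

    path = files("tractterm.data").joinpath("tract_roi_centroids_mni.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
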