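"""NIfTI / TCK / TSV readers and writers.

All volumes are stored as NIfTI-1 with the grid's voxel-to-world affine;
streamline sets as TCK (world mm, RAS); seed sets as 3-column 0-based TSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid, check_same_grid


def grid_from_image(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=float(zooms[0]),
        affine=np.asarray(img.affine, dtype=float),
    )


def read_volume(path: str | Path, reference: VolumeGrid | None = None):
    """Read a NIfTI volume.

    Returns ``(data, grid)``.  If ``reference`` is given, the file's grid must
    match it (shape and affine), otherwise a :class:`GridMismatchError` names
    both grids.
    """
    img = nib.load(str(path))
    grid = grid_from_image(img)
    if reference is not None:
        check_same_grid(reference, grid, what=f"reference and {path}")
    data = np.asanyarray(img.dataobj)
    return data, grid


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI-1, preserving dtype (bool stored as uint8)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, grid.affine)
    img.header.set_zooms((grid.voxel_size,) * 3 + (1.0,) * (arr.ndim - 3))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img.to_filename(str(path))
    return path


def write_seeds_tsv(indices: np.ndarray, path: str | Path) -> Path:
    """Seed voxel indices as a 0-based TSV with columns i, j, k."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(indices, dtype=int), columns=["i", "j", "k"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_seeds_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[["i", "j", "k"]].to_numpy(dtype=np.int64)


def write_tck(streamlines, path: str | Path) -> Path:
    """Write streamlines (sequences of world-mm points) as a TCK file."""
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.tck import TckFile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = [np.asarray(s.points if hasattr(s, "points") else s, dtype=np.float32)
           for s in streamlines]
    tractogram = Tractogram(pts, affine_to_rasmm=np.eye(4))
    TckFile(tractogram).save(str(path))
    return path


def read_tck(path: str | Path) -> list[np.ndarray]:
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in tck.tractogram.streamlines]
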