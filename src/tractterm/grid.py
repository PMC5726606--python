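"""Voxel lattice with a voxel-to-world (RAS mm) mapping.

Every volume in the pipeline lives on a :class:`VolumeGrid` — a 3-D lattice of
isotropic-or-not voxels with an affine mapping voxel indices to world
millimetres.  Voxel membership of a world point uses nearest-voxel rounding,
i.e. voxel ``i`` owns the half-open interval ``[i - 0.5, i + 0.5)`` along each
axis in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _default_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    # RAS, diagonal scaling, world origin at the lattice centre
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    aff[:3, 3] = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_size
    return aff


@dataclass(frozen=True)
class VolumeGrid:
    """Shape + affine of the common volumetric space.

    Parameters
    ----------
    shape : tuple of int
        Voxels along each axis; strictly positive.
    voxel_size : float
        Isotropic voxel edge in mm (kept for convenience; the affine is
        authoritative).
    affine : (4, 4) ndarray, optional
        Voxel-to-world mapping.  Defaults to a diagonal RAS affine with the
        world origin at the centre of the lattice.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        aff = self.affine
        if aff is None:
            aff = _default_affine(shape, float(self.voxel_size))
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", float(self.voxel_size))
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "_inv_affine", np.linalg.inv(aff))

    # -- coordinate transforms -------------------------------------------------

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres.  ``ijk`` is (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel_continuous(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = self._inv_affine  # type: ignore[attr-defined]
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points; may fall outside the grid."""
        cont = self.world_to_voxel_continuous(xyz)
        return np.floor(cont + 0.5).astype(np.int64)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean: are voxel indices within the lattice bounds?"""
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=-1)

    # -- convenience -----------------------------------------------------------

    def world_coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x, y, z of every voxel centre, each shaped like the grid."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1)
        world = self.voxel_to_world(ijk)
        return world[..., 0], world[..., 1], world[..., 2]

    def zeros(self, dtype=float) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if not a.matches(b):
        raise GridMismatchError(
            f"{what} are on different grids: shape {a.shape} affine\n{a.affine}\n"
            f"vs shape {b.shape} affine\n{b.affine}"
        )


def check_shape(volume: np.ndarray, grid: VolumeGrid, what: str = "volume") -> None:
    if tuple(volume.shape) != grid.shape:
        raise GridMismatchError(
            f"{what} has shape {volume.shape}, expected grid shape {grid.shape}"
        )
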