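"""Voxel grids and scalar volumes.

World coordinates are in millimetres with the magnet isocenter at the
origin.  Axis semantics follow the scanner convention used throughout the
package: x = left-right, y = posterior-anterior (+y anterior),
z = inferior-superior (+z superior), with the main field B0 along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["VoxelGrid", "Volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with an affine index→world mapping.

    Parameters
    ----------
    shape
        Number of voxels along each axis (i, j, k).
    index_to_world
        4×4 affine mapping homogeneous 0-based voxel indices to world
        coordinates in mm.  The last row must be ``[0, 0, 0, 1]`` and the
        upper-left 3×3 block must be invertible.
    """

    shape: tuple[int, int, int]
    index_to_world: np.ndarray

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ConfigurationError(f"grid shape must be 3 positive ints, got {shape}")
        aff = np.asarray(self.index_to_world, dtype=float)
        if aff.shape != (4, 4):
            raise ConfigurationError("index_to_world must be a 4x4 matrix")
        if not np.allclose(aff[3], [0.0, 0.0, 0.0, 1.0]):
            raise ConfigurationError("last row of index_to_world must be [0,0,0,1]")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ConfigurationError("index_to_world 3x3 block is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "index_to_world", aff)

    @classmethod
    def centered(cls, shape, voxel_size_mm) -> "VoxelGrid":
        """Axis-aligned grid whose world origin is the grid center."""
        shape = tuple(int(n) for n in np.atleast_1d(shape).repeat(3)[:3]) \
            if np.isscalar(shape) else tuple(int(n) for n in shape)
        vox = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vox)
        aff[:3, 3] = -vox * (np.asarray(shape) - 1) / 2.0
        return cls(shape, aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel spacing (column norms of the affine)."""
        return np.linalg.norm(self.index_to_world[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_coordinates(self):
        """Return (x, y, z) world-coordinate arrays, each of ``self.shape``."""
        ii, jj, kk = np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape),
                                 indexing="ij")
        a = self.index_to_world
        x = a[0, 0] * ii + a[0, 1] * jj + a[0, 2] * kk + a[0, 3]
        y = a[1, 0] * ii + a[1, 1] * jj + a[1, 2] * kk + a[1, 3]
        z = a[2, 0] * ii + a[2, 1] * jj + a[2, 2] * kk + a[2, 3]
        return x, y, z

    def index_to_world_points(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, float)
        return idx @ self.index_to_world[:3, :3].T + self.index_to_world[:3, 3]

    def world_to_index_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        inv = np.linalg.inv(self.index_to_world)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def __eq__(self, other):
        return (isinstance(other, VoxelGrid)
                and self.shape == other.shape
                and np.allclose(self.index_to_world, other.index_to_world))

    def __hash__(self):
        return hash((self.shape, self.index_to_world.tobytes()))


@dataclass
class Volume:
    """A scalar volume bound to a :class:`VoxelGrid`."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"volume shape {self.values.shape} != grid shape {self.grid.shape}")

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.grid)
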