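"""3D scalar volumes with world geometry, plus NIfTI I/O.

Grid convention: ``values[i, j, k]`` with axis 0 along world x when the
direction matrix is the identity.  Zero-based voxel indices address voxel
*centers*: the world coordinate of index ``i`` is
``origin + direction @ (spacing * i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMap"]


@dataclass
class Volume:
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if np.linalg.det(self.direction) <= 0:
            raise ValueError("direction matrix must have determinant +1")

    # ------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_to_world(self, indices) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = idx * self.spacing @ self.direction.T + self.origin
        return pts[0] if np.asarray(indices).ndim == 1 else pts

    def world_to_voxel(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (p - self.origin) @ self.direction / self.spacing
        return idx[0] if np.asarray(points).ndim == 1 else idx

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """Same grid, different data."""
        return replace(self, values=values)

    # ------------------------------------------------------------ I/O
    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values), self.affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        values = np.asarray(img.dataobj)
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        direction = aff[:3, :3] / spacing
        return cls(values=values, spacing=spacing, origin=aff[:3, 3], direction=direction)


@dataclass
class LabelMap:
    """Integer-labeled segmentation volume with a name->label vocabulary."""

    volume: Volume
    labels: dict

    def __post_init__(self):
        if not np.issubdtype(self.volume.values.dtype, np.integer):
            raise ValueError("labelmap values must be integer")

    def mask(self, name: str) -> np.ndarray:
        return self.volume.values == self.labels[name]

    @property
    def names(self):
        return list(self.labels)

    def voxel_count(self, name: str) -> int:
        return int(np.count_nonzero(self.mask(name)))

    def structure_volume_mm3(self, name: str) -> float:
        return self.voxel_count(name) * float(np.prod(self.volume.spacing))

    def centroid_mm(self, name: str) -> np.ndarray:
        """Geometric centroid of a structure, in world mm."""
        idx = np.argwhere(self.mask(name))
        if idx.size == 0:
            raise ValueError(f"structure {name!r} is empty")
        return self.volume.voxel_to_world(idx.mean(axis=0))

    def save(self, path) -> None:
        self.volume.save(path)
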