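"""Rigid (6-DOF) spatial transforms on world millimetre coordinates.

A :class:`RigidTransform` is stored as a 4x4 homogeneous matrix whose
rotation block is orthonormal with determinant +1.  The convention used
throughout the package is *moving-world -> fixed-world*: applying the
transform to a point expressed in the moving volume's world frame yields
the corresponding point in the fixed volume's world frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "sample_rigid_misalignment"]

_ORTHO_TOL = 1e-6


class RigidTransform:
    """A 6-DOF rigid map represented by a 4x4 homogeneous matrix."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.array(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"rigid transform matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a homogeneous rigid matrix must be [0 0 0 1]")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        m[3] = (0.0, 0.0, 0.0, 1.0)
        self.matrix = m

    # ---------------------------------------------------------------- constructors
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def from_params(cls, rotvec_deg, translation_mm, center=None) -> "RigidTransform":
        """Build from a rotation vector (degrees) and a translation (mm).

        The rotation is applied about ``center`` (world mm, default origin),
        then the translation is added:  x -> R (x - c) + c + t.
        """
        rotvec_deg = np.asarray(rotvec_deg, dtype=float)
        t = np.asarray(translation_mm, dtype=float)
        r = Rotation.from_rotvec(rotvec_deg, degrees=True).as_matrix()
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c - r @ c + t
        return cls(m)

    @classmethod
    def from_text(cls, path) -> "RigidTransform":
        return cls(np.loadtxt(path).reshape(4, 4))

    # ---------------------------------------------------------------- properties
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    # ---------------------------------------------------------------- algebra
    def apply(self, points) -> np.ndarray:
        """Map one point (3,) or many points (N, 3) through the transform."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (``other`` is applied first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-8) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(angle={self.rotation_angle_deg:.3f} deg, t={self.translation})"

    # ---------------------------------------------------------------- serialization
    def to_text(self, path) -> None:
        """Write the 4x4 matrix as plain text, row-major."""
        np.savetxt(path, self.matrix, fmt="%.17g")


def sample_rigid_misalignment(
    max_rotation_deg: float,
    max_translation_mm: float,
    seed: int,
    center=None,
) -> RigidTransform:
    """Draw a random rigid transform with bounded rotation and translation.

    The rotation axis is uniform on the sphere, the angle uniform on
    ``[0, max_rotation_deg]`` and applied about ``center`` (default the
    origin); the translation is uniform in the ball of radius
    ``max_translation_mm``.  Deterministic for a fixed seed.
    """
    if max_rotation_deg < 0 or max_translation_mm < 0:
        raise ValueError("misalignment bounds must be non-negative")
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
    angle = rng.uniform(0.0, max_rotation_deg)
    tdir = rng.normal(size=3)
    n = np.linalg.norm(tdir)
    tdir = tdir / n if n > 0 else np.array([1.0, 0.0, 0.0])
    # radius ~ u^(1/3): uniform density in the ball
    tnorm = max_translation_mm * rng.uniform() ** (1.0 / 3.0)
    return RigidTransform.from_params(axis * angle, tdir * tnorm, center=center)
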