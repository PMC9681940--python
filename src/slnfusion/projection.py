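"""Pinhole-camera rendering of fused 3D segments into 2D overlay masks.

The camera stands in for the laparoscope viewing the phantom: an ideal
(undistorted) pinhole with focal length in pixels, viewing the
intraoperative scene.  Rendering projects every segment voxel center and
solidifies the resulting pixel cloud morphologically; occlusion is
deliberately ignored because the overlay metrics are defined on plain 2D
surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .segmentation import Structure
from .transforms import RigidTransform
from .volume import Volume

__all__ = ["CameraModel", "Mask2D", "default_camera", "project_point", "render_segment_mask", "make_overlay_pair"]


@dataclass
class CameraModel:
    """Ideal pinhole camera: intrinsics plus a world->camera rigid pose."""

    focal_length: float  # pixels
    principal_point: Tuple[float, float]  # (cx, cy) pixels
    image_size: Tuple[int, int]  # (width, height) pixels
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal length must be strictly positive")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("principal point must lie inside the image")


def default_camera(look_at=(100.0, 90.0, 70.0), distance_mm: float = 450.0) -> CameraModel:
    """Endoscope-like default: f = 1000 px, 1280x720, viewing the SLN region.

    The camera sits ``distance_mm`` anterior to ``look_at`` and looks
    along +y of the board frame; camera x follows world x and camera y
    points along -z so the image v axis runs downward.
    """
    r = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
    center = np.asarray(look_at, dtype=float) - np.array([0.0, distance_mm, 0.0])
    pose = RigidTransform.from_rotation_translation(r, -r @ center)
    return CameraModel(focal_length=1000.0, principal_point=(640.0, 360.0), image_size=(1280, 720), pose=pose)


@dataclass
class Mask2D:
    """Binary pixel mask; ``data[v, u]`` with 0-based pixel indices."""

    data: np.ndarray
    provenance: str = "ar"  # {"ar", "ground_truth"}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("a 2D pixel grid is required")

    @property
    def area(self) -> int:
        return int(self.data.sum())

    def save_png(self, path) -> None:
        Image.fromarray((self.data * np.uint8(255))).save(str(path))

    @classmethod
    def load_png(cls, path, provenance: str = "ar") -> "Mask2D":
        arr = np.asarray(Image.open(str(path)).convert("L"))
        return cls(data=arr > 127, provenance=provenance)


def project_point(camera: CameraModel, world_point) -> np.ndarray:
    """Pinhole projection u = f x/z + cx, v = f y/z + cy (camera frame)."""
    p = camera.pose.apply(np.asarray(world_point, dtype=float))
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p[:, 2] <= 0):
        raise ValueError("point has non-positive depth in the camera frame")
    uv = camera.focal_length * p[:, :2] / p[:, 2:3] + np.asarray(camera.principal_point)
    return uv[0] if single else uv


def render_segment_mask(camera: CameraModel, segment: Structure, grid: Volume, transform: RigidTransform) -> Mask2D:
    """Project a 3D segment into the camera and solidify its pixel footprint.

    Every voxel center of the segment mask (on ``grid``) is mapped by
    ``transform`` into the viewed (intraoperative) world, projected, and
    rasterized; morphological closing (3x3) plus hole filling produce a
    solid footprint.  Pixels outside the image are clipped.
    """
    idx = np.argwhere(segment.mask)
    if idx.size == 0:
        raise ValueError(f"segment {segment.name!r} is empty")
    world = transform.apply(grid.voxel_to_world(idx.astype(float)))
    cam = camera.pose.apply(world)
    cam = cam[cam[:, 2] > 0]
    w, h = camera.image_size
    img = np.zeros((h, w), dtype=bool)
    if cam.shape[0] == 0:
        warnings.warn("segment is entirely behind the camera; mask is empty", stacklevel=2)
        return Mask2D(data=img)
    uv = camera.focal_length * cam[:, :2] / cam[:, 2:3] + np.asarray(camera.principal_point)
    px = np.round(uv).astype(int)
    keep = (px[:, 0] >= 0) & (px[:, 0] < w) & (px[:, 1] >= 0) & (px[:, 1] < h)
    px = px[keep]
    if px.shape[0] == 0:
        warnings.warn("segment projects entirely outside the image; mask is empty", stacklevel=2)
        return Mask2D(data=img)
    img[px[:, 1], px[:, 0]] = True
    # the projected lattice of voxel centers has pixel pitch ~ f*h/z; the
    # closing element must bridge that pitch or the footprint stays porous
    z_med = float(np.median(cam[:, 2]))
    pitch_px = camera.focal_length * float(np.max(grid.spacing)) / z_med
    k = max(int(np.ceil(pitch_px)) + 2, 3)
    if k % 2 == 0:
        k += 1
    img = ndimage.binary_closing(img, structure=np.ones((k, k), dtype=bool))
    # voxels are boxes, not points: grow the footprint by the projected
    # half-voxel extent so the silhouette matches the continuous structure
    half = int(pitch_px / 2.0)
    if half > 0:
        img = ndimage.binary_dilation(img, structure=np.ones((2 * half + 1, 2 * half + 1), dtype=bool))
    img = ndimage.binary_fill_holes(img)
    return Mask2D(data=img)


def make_overlay_pair(
    camera: CameraModel,
    segment: Structure,
    grid: Volume,
    t_estimated: RigidTransform,
    t_true: RigidTransform,
) -> Tuple[Mask2D, Mask2D]:
    """Render the AR mask (estimated transform) and its ground-truth twin.

    s1 is what the guidance system would draw (segment mapped through the
    *estimated* registration); s2 is where the structure actually is
    (mapped through the *true* transform), standing in for the node seen
    in the endoscopic image.
    """
    s1 = render_segment_mask(camera, segment, grid, t_estimated)
    s1.provenance = "ar"
    s2 = render_segment_mask(camera, segment, grid, t_true)
    s2.provenance = "ground_truth"
    return s1, s2
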