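"""Digital twin of the pelvic SLN phantom and simulated acquisitions.

The physical object being emulated is a gelatin-embedded pelvic phantom:
a radiopaque bone arch, a tube-based iliac vessel tree ending in two
fillable spheres that stand in for sentinel lymph nodes (8 mm left,
15 mm right), and a calibration board of spherical fiducials used to
compute cross-modality transforms.

Two virtual scanners image the phantom: a CT-like modality (fine voxels,
Gaussian noise) and a SPECT-like modality (4.4 mm voxels, Gaussian PSF
blur, Poisson counting noise) in which only the radiotracer-filled SLN
spheres are active.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Literal, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .transforms import RigidTransform, sample_rigid_misalignment  # noqa: F401  (re-export)
from .volume import LabelMap, Volume

__all__ = [
    "BoneArch",
    "PhantomSpec",
    "ModalityModel",
    "LABELS",
    "FIDUCIAL_LABEL_BASE",
    "build_phantom_labelmap",
    "render_ct",
    "render_spect",
    "sample_rigid_misalignment",
    "default_ct_model",
    "default_spect_model",
]

Vec3 = Tuple[float, float, float]

# fixed label vocabulary; fiducial k gets FIDUCIAL_LABEL_BASE + k
LABELS: Dict[str, int] = {"background": 0, "bone": 1, "vessel": 2, "sln_left": 3, "sln_right": 4}
FIDUCIAL_LABEL_BASE = 10


class BoneArch(BaseModel):
    """Posterior half-annular shell standing in for the pelvic ring.

    Voxels belong to the arch when their xy-plane distance from the axis
    through ``center`` lies in [inner_radius, outer_radius], their y
    coordinate is at least ``y_min`` (posterior cut) and their z lies in
    ``z_range``.
    """

    model_config = ConfigDict(extra="forbid")

    center: Vec3 = (100.0, 85.0, 70.0)
    inner_radius: float = 54.0
    outer_radius: float = 62.0
    y_min: float = 88.0
    z_range: Tuple[float, float] = (45.0, 95.0)

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("bone arch radii must satisfy 0 < inner < outer")
        if self.z_range[0] >= self.z_range[1]:
            raise ValueError("bone arch z_range must be increasing")
        return self


class PhantomSpec(BaseModel):
    """Parametric description of the phantom in its own (board) frame.

    World frame: right-handed, axes aligned with the phantom board,
    units mm, origin at the field-of-view corner.
    """

    model_config = ConfigDict(extra="forbid")

    field_of_view: Vec3 = (200.0, 160.0, 140.0)
    sln_left_diameter: float = 8.0
    sln_right_diameter: float = 15.0
    sln_centers: Tuple[Vec3, Vec3] = ((65.0, 90.0, 70.0), (135.0, 90.0, 70.0))
    vessel_paths: List[List[Vec3]] = Field(
        default_factory=lambda: [
            [(100.0, 30.0, 70.0), (100.0, 60.0, 70.0), (65.0, 90.0, 70.0)],
            [(100.0, 60.0, 70.0), (135.0, 90.0, 70.0)],
        ]
    )
    vessel_radius: float = 4.0
    bone: BoneArch = Field(default_factory=BoneArch)
    fiducials: List[Vec3] = Field(
        default_factory=lambda: [
            (55.0, 45.0, 45.0),
            (145.0, 45.0, 45.0),
            (55.0, 45.0, 105.0),
            (145.0, 45.0, 105.0),
            (100.0, 38.0, 60.0),
            (75.0, 52.0, 92.0),
        ]
    )
    fiducial_radius: float = 5.0

    # ------------------------------------------------------------ validation
    @model_validator(mode="after")
    def _check(self):
        if self.sln_left_diameter <= 0 or self.sln_right_diameter <= 0:
            raise ValueError("SLN sphere diameters must be strictly positive")
        if self.vessel_radius <= 0 or self.fiducial_radius <= 0:
            raise ValueError("tube and fiducial radii must be strictly positive")
        if self.sln_centers[0][0] >= self.sln_centers[1][0]:
            raise ValueError("left SLN center must have strictly smaller x than the right one")
        if len(self.fiducials) < 4:
            raise ValueError("at least 4 fiducials are required")
        f = np.asarray(self.fiducials, dtype=float)
        sv = np.linalg.svd(f - f.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-6 * max(sv[0], 1.0):
            raise ValueError("fiducials are collinear")
        if sv[2] < 1e-6 * max(sv[0], 1.0):
            raise ValueError("fiducials are coplanar")
        if len(set(map(tuple, self.fiducials))) != len(self.fiducials):
            raise ValueError("fiducial positions must be unique")
        self._check_inside_fov()
        return self

    def _check_inside_fov(self):
        fov = np.asarray(self.field_of_view)

        def inside(lo, hi, what):
            if np.any(np.asarray(lo) < 0) or np.any(np.asarray(hi) > fov):
                raise ValueError(f"{what} extends outside the field of view")

        for name, c, d in (
            ("sln_left", self.sln_centers[0], self.sln_left_diameter),
            ("sln_right", self.sln_centers[1], self.sln_right_diameter),
        ):
            c = np.asarray(c)
            inside(c - d / 2, c + d / 2, name)
        for path in self.vessel_paths:
            p = np.asarray(path, dtype=float)
            inside(p.min(axis=0) - self.vessel_radius, p.max(axis=0) + self.vessel_radius, "vessel tree")
        for k, fpt in enumerate(self.fiducials):
            fpt = np.asarray(fpt)
            inside(fpt - self.fiducial_radius, fpt + self.fiducial_radius, f"fiducial_{k}")
        bx, by, _ = self.bone.center
        r = self.bone.outer_radius
        inside(
            (bx - r, self.bone.y_min, self.bone.z_range[0]),
            (bx + r, by + r, self.bone.z_range[1]),
            "bone arch",
        )

    # ------------------------------------------------------------ helpers
    @property
    def fov_center(self) -> np.ndarray:
        return np.asarray(self.field_of_view) / 2.0

    def fiducial_label(self, k: int) -> int:
        return FIDUCIAL_LABEL_BASE + k

    def label_vocabulary(self) -> Dict[str, int]:
        vocab = dict(LABELS)
        for k in range(len(self.fiducials)):
            vocab[f"fiducial_{k}"] = self.fiducial_label(k)
        return vocab


class ModalityModel(BaseModel):
    """Intensity/noise/resolution model of one virtual scanner.

    ``tissue_intensities`` maps structure names (or their base name, e.g.
    ``fiducial`` for every ``fiducial_k``) to mean intensity: HU-like for
    CT, activity-like (MBq/mL-scaled) for SPECT.  ``acquisition_metadata``
    records provenance-only parameters of the emulated protocol; they do
    not influence the simulation.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["CT", "SPECT"]
    tissue_intensities: Dict[str, float]
    voxel_size_mm: float
    psf_fwhm_mm: float = 0.0
    noise_sigma: float = 0.0  # CT: Gaussian sigma in intensity units
    poisson_scale: float = 0.0  # SPECT: expected counts per activity unit
    acquisition_metadata: Dict[str, object] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be strictly positive")
        if self.psf_fwhm_mm < 0 or self.noise_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise and PSF parameters must be non-negative")
        if self.kind == "SPECT":
            if any(v < 0 for v in self.tissue_intensities.values()):
                raise ValueError("SPECT activities must be non-negative")
            hot = {k for k, v in self.tissue_intensities.items() if v > 0}
            if not hot <= {"sln", "sln_left", "sln_right", "background"}:
                raise ValueError("SPECT activity must be confined to SLN labels (plus optional background)")
        return self


def default_ct_model(voxel_size_mm: float = 1.0, noise_sigma: float = 15.0) -> ModalityModel:
    """CT-like scanner: contrast-filled SLNs, radiopaque bone and fiducials."""
    return ModalityModel(
        kind="CT",
        voxel_size_mm=voxel_size_mm,
        noise_sigma=noise_sigma,
        tissue_intensities={
            "background": 0.0,
            "bone": 1200.0,
            "vessel": 300.0,
            "sln": 600.0,
            "fiducial": 2500.0,
        },
    )


def default_spect_model(
    voxel_size_mm: float = 4.4,
    psf_fwhm_mm: float = 10.0,
    sln_activity: float = 12.0,
    poisson_scale: float = 25.0,
) -> ModalityModel:
    """SPECT-like scanner: hot SLN spheres (12 MBq/mL-scaled 99mTc), PSF blur, Poisson noise.

    The emulated acquisition protocol (projections, reconstruction, energy
    windows) is kept as metadata only.
    """
    return ModalityModel(
        kind="SPECT",
        voxel_size_mm=voxel_size_mm,
        psf_fwhm_mm=psf_fwhm_mm,
        poisson_scale=poisson_scale,
        tissue_intensities={"background": 0.0, "sln": sln_activity},
        acquisition_metadata={
            "matrix_size": 128,
            "n_projections": 60,
            "seconds_per_projection": 30,
            "reconstruction": "OSEM 8 iterations x 8 subsets",
            "photopeak_window": "140.5 keV +/- 10%",
            "scatter_window": "120 keV +/- 5%",
        },
    )


# ---------------------------------------------------------------------- labelmap
def _grid_axes(fov: np.ndarray, voxel: np.ndarray):
    shape = np.maximum(np.round(fov / voxel).astype(int), 1)
    axes = [(np.arange(n) + 0.5) * h for n, h in zip(shape, voxel)]
    return shape, axes


def _fill_sphere(values, axes, voxel, center, radius, label):
    lo = [np.searchsorted(ax, c - radius - h) for ax, c, h in zip(axes, center, voxel)]
    hi = [np.searchsorted(ax, c + radius + h) for ax, c, h in zip(axes, center, voxel)]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    xs, ys, zs = (ax[s] for ax, s in zip(axes, sl))
    d2 = (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )
    values[sl][d2 <= radius**2] = label


def _fill_capsule(values, axes, voxel, p0, p1, radius, label):
    """Tube segment with spherical caps (distance-to-segment <= radius)."""
    lo_pt = np.minimum(p0, p1) - radius
    hi_pt = np.maximum(p0, p1) + radius
    lo = [np.searchsorted(ax, c - h) for ax, c, h in zip(axes, lo_pt, voxel)]
    hi = [np.searchsorted(ax, c + h) for ax, c, h in zip(axes, hi_pt, voxel)]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    xs, ys, zs = (ax[s] for ax, s in zip(axes, sl))
    px = xs[:, None, None] - p0[0]
    py = ys[None, :, None] - p0[1]
    pz = zs[None, None, :] - p0[2]
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        t = 0.0
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / len2, 0.0, 1.0)
    d2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    values[sl][d2 <= radius**2] = label


def build_phantom_labelmap(spec: PhantomSpec, voxel_size) -> LabelMap:
    """Voxelize the phantom: a voxel is labeled when its center lies inside a structure.

    Overlaps resolve by fixed precedence fiducial > sln > vessel > bone >
    background (later assignment wins below).
    """
    voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if np.any(voxel <= 0):
        raise ValueError("voxel size must be strictly positive")
    fov = np.asarray(spec.field_of_view, dtype=float)
    shape, axes = _grid_axes(fov, voxel)
    values = np.zeros(tuple(shape), dtype=np.int16)

    # bone arch (lowest precedence above background)
    b = spec.bone
    xs, ys, zs = axes
    rho2 = (xs[:, None] - b.center[0]) ** 2 + (ys[None, :] - b.center[1]) ** 2
    ring = (rho2 >= b.inner_radius**2) & (rho2 <= b.outer_radius**2) & (ys[None, :] >= b.y_min)
    zok = (zs >= b.z_range[0]) & (zs <= b.z_range[1])
    values[ring[:, :, None] & zok[None, None, :]] = LABELS["bone"]

    for path in spec.vessel_paths:
        pts = [np.asarray(p, dtype=float) for p in path]
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _fill_capsule(values, axes, voxel, p0, p1, spec.vessel_radius, LABELS["vessel"])

    _fill_sphere(values, axes, voxel, np.asarray(spec.sln_centers[0]), spec.sln_left_diameter / 2, LABELS["sln_left"])
    _fill_sphere(values, axes, voxel, np.asarray(spec.sln_centers[1]), spec.sln_right_diameter / 2, LABELS["sln_right"])

    for k, f in enumerate(spec.fiducials):
        _fill_sphere(values, axes, voxel, np.asarray(f, dtype=float), spec.fiducial_radius, spec.fiducial_label(k))

    vol = Volume(values=values, spacing=voxel, origin=voxel / 2.0)
    return LabelMap(volume=vol, labels=spec.label_vocabulary())


# ---------------------------------------------------------------------- rendering
def _intensity_lut(labels: Dict[str, int], tissue_intensities: Dict[str, float]) -> np.ndarray:
    lut = np.zeros(max(labels.values()) + 1, dtype=np.float64)
    for name, lab in labels.items():
        base = name.split("_")[0]
        if name in tissue_intensities:
            lut[lab] = tissue_intensities[name]
        elif base in tissue_intensities:
            lut[lab] = tissue_intensities[base]
        elif name.startswith("sln") and "sln" in tissue_intensities:
            lut[lab] = tissue_intensities["sln"]
        else:
            lut[lab] = tissue_intensities.get("background", 0.0)
    return lut


def _resample_labels(labelmap: LabelMap, pose: RigidTransform, out_voxel: float) -> Volume:
    """Nearest-neighbor resampling of the posed phantom onto a scanner grid.

    The scanner grid covers the same field of view as the labelmap; the
    phantom is rigidly moved by ``pose`` within that field (structure at
    board point p images at scanner point pose(p)).
    """
    src = labelmap.volume
    fov = src.spacing * np.asarray(src.shape)
    voxel = np.broadcast_to(np.asarray(out_voxel, dtype=float), (3,)).copy()
    shape, _ = _grid_axes(fov, voxel)
    out_origin = voxel / 2.0
    # out index -> world (scanner) -> pose^-1 -> board world -> labelmap index
    a = np.linalg.inv(src.affine) @ pose.inverse().matrix
    m = a[:3, :3] @ np.diag(voxel)
    off = a[:3, :3] @ out_origin + a[:3, 3]
    ii = np.arange(shape[0])[:, None, None]
    jj = np.arange(shape[1])[None, :, None]
    kk = np.arange(shape[2])[None, None, :]
    coords = [m[d, 0] * ii + m[d, 1] * jj + m[d, 2] * kk + off[d] for d in range(3)]
    out = ndimage.map_coordinates(src.values, coords, order=0, mode="constant", cval=0)
    return Volume(values=out, spacing=voxel, origin=out_origin)


def _check_slns_visible(resampled: Volume, labels: Dict[str, int]):
    present = [
        bool(np.any(resampled.values == labels[name])) for name in ("sln_left", "sln_right") if name in labels
    ]
    if present and not any(present):
        raise ValueError("pose moved all SLNs outside the field of view")
    if present and not all(present):
        warnings.warn("one SLN left the field of view under the given pose", stacklevel=3)


def render_ct(labelmap: LabelMap, model: ModalityModel, pose: RigidTransform, seed: int) -> Volume:
    """Simulate a CT-like acquisition: pose, resample, intensity map, Gaussian noise."""
    if model.kind != "CT":
        raise ValueError("render_ct requires a CT modality model")
    res = _resample_labels(labelmap, pose, model.voxel_size_mm)
    _check_slns_visible(res, labelmap.labels)
    lut = _intensity_lut(labelmap.labels, model.tissue_intensities)
    values = lut[res.values].astype(np.float32)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.noise_sigma, size=values.shape).astype(np.float32)
    return res.with_values(values)


def render_spect(labelmap: LabelMap, model: ModalityModel, pose: RigidTransform, seed: int) -> Volume:
    """Simulate a SPECT-like acquisition: pose, resample activity, PSF blur, Poisson noise.

    Tomographic reconstruction is not modeled; the acquisition protocol is
    carried as metadata on the modality model.
    """
    if model.kind != "SPECT":
        raise ValueError("render_spect requires a SPECT modality model")
    res = _resample_labels(labelmap, pose, model.voxel_size_mm)
    lut = _intensity_lut(labelmap.labels, model.tissue_intensities)
    if np.any(lut < 0):
        raise ValueError("negative activity is not physical")
    values = lut[res.values].astype(np.float64)
    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / res.spacing
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant", cval=0.0)
    if model.poisson_scale > 0:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(values * model.poisson_scale)
        values = counts / model.poisson_scale
    return res.with_values(values.astype(np.float32))
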