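"""Structure extraction from rendered volumes.

CT structures are found by intensity windowing plus 26-connected
component analysis; SPECT SLN hotspots by an isocontour at a fraction of
the global maximum.  CT centroids are geometric (unweighted); SPECT
hotspot centroids are intensity-weighted, which under heavy PSF blur is
the better estimator of the underlying sphere center.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "Structure",
    "StructureSet",
    "DEFAULT_CT_THRESHOLDS",
    "dice",
    "segment_ct",
    "segment_spect_hotspots",
    "assign_left_right",
    "detect_fiducials",
]

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: intensity windows matched to :func:`slnfusion.phantom.default_ct_model`
DEFAULT_CT_THRESHOLDS: Dict[str, Tuple[float, float]] = {
    "vessel": (150.0, 450.0),
    "sln": (450.0, 900.0),
    "bone": (900.0, 1800.0),
    "fiducial": (2000.0, 1e9),
}


@dataclass
class Structure:
    name: str
    mask: np.ndarray  # boolean, on the grid of StructureSet.grid
    centroid_mm: np.ndarray
    volume_mm3: float


@dataclass
class StructureSet:
    """Named binary masks sharing one reference grid."""

    grid: Volume  # geometry carrier; its values are not used
    structures: Dict[str, Structure] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    @property
    def names(self) -> List[str]:
        return list(self.structures)

    def add(self, s: Structure) -> None:
        if not s.mask.any():
            raise ValueError(f"structure {s.name!r} has an empty mask")
        self.structures[s.name] = s

    def summary(self) -> List[dict]:
        return [
            {"name": s.name, "centroid_mm": s.centroid_mm.tolist(), "volume_mm3": s.volume_mm3}
            for s in self.structures.values()
        ]

    def save(self, labelmap_path, summary_path) -> None:
        """Export as one NIfTI labelmap (1-based labels in insertion order) + JSON summary."""
        import json
        from pathlib import Path

        values = np.zeros(self.grid.shape, dtype=np.int16)
        labels = {}
        for i, (name, s) in enumerate(self.structures.items(), start=1):
            values[s.mask] = i
            labels[name] = i
        self.grid.with_values(values).save(labelmap_path)
        Path(summary_path).write_text(
            json.dumps({"labels": labels, "structures": self.summary()}, indent=2, sort_keys=True) + "\n"
        )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric Dice overlap of two binary masks (internal diagnostic)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _components(mask: np.ndarray, min_voxels: int) -> List[np.ndarray]:
    """26-connected components of at least ``min_voxels``, largest first.

    Ties in size break on the lexicographically smallest voxel index so
    the result never depends on scan order.
    """
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return []
    sizes = np.bincount(lab.ravel())[1:]
    comps = []
    for i in np.flatnonzero(sizes >= min_voxels):
        comps.append(lab == i + 1)
    comps.sort(key=lambda m: (-int(m.sum()), tuple(np.argwhere(m)[0])))
    return comps


def _geom_structure(name: str, mask: np.ndarray, grid: Volume) -> Structure:
    idx = np.argwhere(mask)
    centroid = grid.voxel_to_world(idx.mean(axis=0))
    vol = float(idx.shape[0] * np.prod(grid.spacing))
    return Structure(name=name, mask=mask, centroid_mm=np.asarray(centroid), volume_mm3=vol)


def segment_ct(
    volume: Volume,
    thresholds: Optional[Dict[str, Tuple[float, float]]] = None,
    min_component_voxels: int = 10,
) -> StructureSet:
    """Window-and-label segmentation of a CT-like render.

    For the ``sln`` window the two largest components become
    ``sln_candidate_1``/``sln_candidate_2`` (resolve sides with
    :func:`assign_left_right`); ``fiducial`` components are enumerated
    ``fiducial_det_k``; any other window yields a single union structure.
    """
    thresholds = dict(DEFAULT_CT_THRESHOLDS if thresholds is None else thresholds)
    ivals = sorted(thresholds.items(), key=lambda kv: kv[1][0])
    for (na, a), (nb, b) in zip(ivals[:-1], ivals[1:]):
        if a[1] > b[0]:
            raise ValueError(f"threshold intervals for {na!r} and {nb!r} overlap")
    v = volume.values
    out = StructureSet(grid=volume.with_values(np.zeros(volume.shape, dtype=np.uint8)))
    for name, (lo, hi) in thresholds.items():
        comps = _components((v >= lo) & (v <= hi), min_component_voxels)
        if not comps:
            raise ValueError(f"no voxels found for structure {name!r} in [{lo}, {hi}]")
        if name == "sln":
            for i, m in enumerate(comps[:2]):
                out.add(_geom_structure(f"sln_candidate_{i + 1}", m, volume))
        elif name == "fiducial":
            comps.sort(key=lambda m: tuple(np.round(np.argwhere(m).mean(axis=0), 3)))
            for i, m in enumerate(comps):
                out.add(_geom_structure(f"fiducial_det_{i}", m, volume))
        else:
            union = np.logical_or.reduce(comps)
            out.add(_geom_structure(name, union, volume))
    return out


def segment_spect_hotspots(volume: Volume, fraction_of_max: float = 0.10) -> StructureSet:
    """Isocontour hotspot extraction from a SPECT-like render.

    The mask is ``values >= fraction_of_max * max``; the two largest
    26-connected components become SLN candidates with intensity-weighted
    centroids.
    """
    if not 0.0 < fraction_of_max < 1.0:
        raise ValueError("fraction_of_max must lie in (0, 1)")
    v = volume.values
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("SPECT volume has no positive activity")
    comps = _components(v >= fraction_of_max * vmax, min_voxels=1)
    if len(comps) < 2:
        raise ValueError(f"expected at least 2 hotspots, found {len(comps)}")
    out = StructureSet(grid=volume.with_values(np.zeros(volume.shape, dtype=np.uint8)))
    for i, m in enumerate(comps[:2]):
        idx = np.argwhere(m)
        w = v[m].astype(float)
        centroid = volume.voxel_to_world((idx * w[:, None]).sum(axis=0) / w.sum())
        out.add(
            Structure(
                name=f"sln_candidate_{i + 1}",
                mask=m,
                centroid_mm=np.asarray(centroid),
                volume_mm3=float(idx.shape[0] * np.prod(volume.spacing)),
            )
        )
    return out


def assign_left_right(structures: StructureSet, tol: float = 1e-6) -> StructureSet:
    """Name the two SLN candidates by first world coordinate (smaller x = left).

    On an x tie the larger-volume candidate becomes the right node; the
    tie-break is logged.
    """
    cands = [s for n, s in structures.structures.items() if n.startswith("sln_candidate")]
    if len(cands) != 2:
        raise ValueError(f"expected exactly 2 SLN candidates, found {len(cands)}")
    a, b = cands
    if abs(a.centroid_mm[0] - b.centroid_mm[0]) <= tol:
        left, right = sorted(cands, key=lambda s: s.volume_mm3)
        logger.warning(
            "SLN x-coordinate tie (%.6f vs %.6f); assigning larger volume (%.1f mm^3) to the right",
            a.centroid_mm[0],
            b.centroid_mm[0],
            right.volume_mm3,
        )
    else:
        left, right = sorted(cands, key=lambda s: s.centroid_mm[0])
    out = StructureSet(grid=structures.grid)
    for n, s in structures.structures.items():
        if not n.startswith("sln_candidate"):
            out.add(s)
    out.add(replace(left, name="sln_left"))
    out.add(replace(right, name="sln_right"))
    return out


def _match_by_distances(detected: np.ndarray, expected: np.ndarray) -> List[int]:
    """Rigid-invariant correspondence: choose the assignment of detections to
    expected points that best reproduces the expected inter-point distance
    matrix (exhaustive over permutations)."""
    n = len(expected)
    if len(detected) > 9:
        raise ValueError("exhaustive fiducial matching supports at most 9 points")
    d_exp = np.linalg.norm(expected[:, None] - expected[None, :], axis=-1)
    d_det = np.linalg.norm(detected[:, None] - detected[None, :], axis=-1)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(len(detected)), n):
        p = list(perm)
        cost = float(np.abs(d_det[np.ix_(p, p)] - d_exp).sum())
        if cost < best_cost - 1e-12:
            best_cost, best = cost, p
    return best


def detect_fiducials(
    volume: Volume,
    expected: Sequence,
    threshold: Optional[Tuple[float, float]] = None,
    min_component_voxels: int = 5,
) -> np.ndarray:
    """Locate the calibration-board fiducials and order them like ``expected``.

    Detection is intensity windowing (default: the fiducial CT window) plus
    component analysis; matching to the expected ordering is rigid-invariant,
    by exhaustive assignment on inter-point distance matrices, so it holds
    under any repositioning of the board between sessions.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.ndim != 2 or expected.shape[0] < 4 or expected.shape[1] != 3:
        raise ValueError("at least 4 expected fiducial positions (x, y, z) are required")
    lo, hi = threshold if threshold is not None else DEFAULT_CT_THRESHOLDS["fiducial"]
    comps = _components((volume.values >= lo) & (volume.values <= hi), min_component_voxels)
    if len(comps) < len(expected):
        raise ValueError(f"detected {len(comps)} fiducials, expected {len(expected)}")
    if len(comps) > 9:  # keep the largest blobs; the assignment picks the best subset
        comps = comps[:9]
    centroids = np.array([volume.voxel_to_world(np.argwhere(m).mean(axis=0)) for m in comps])
    order = _match_by_distances(centroids, expected)
    return centroids[order]
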