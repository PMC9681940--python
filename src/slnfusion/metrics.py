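"""AR overlay accuracy statistics on 2D mask pairs.

Two quantities summarize how well the augmented-reality surface s1 lands
on the actually-visible surface s2:

* the normalized barycenter distance d(b1, b2) / r, with r = sqrt(area/pi)
  the pseudo-radius of s1 (a ratio below 1 means the AR barycenter falls
  inside one pseudo-radius of the true one);
* the coverage rate |s1 ∩ s2| / |s2|, the fraction of the visible surface
  that the AR surface covers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, List

import numpy as np
import pandas as pd

from .projection import Mask2D

__all__ = [
    "OverlayReport",
    "barycenter",
    "pseudo_radius",
    "normalized_barycenter_distance",
    "coverage_rate",
    "overlay_report",
    "reports_to_frame",
]


def _check_same_size(s1: Mask2D, s2: Mask2D) -> None:
    if s1.data.shape != s2.data.shape:
        raise ValueError(f"mask sizes differ: {s1.data.shape} vs {s2.data.shape}")


def barycenter(mask: Mask2D) -> np.ndarray:
    """Arithmetic mean (u, v) of set-pixel coordinates, sub-pixel precision."""
    vs, us = np.nonzero(mask.data)
    if us.size == 0:
        raise ValueError("cannot take the barycenter of an empty mask")
    return np.array([us.mean(), vs.mean()])


def pseudo_radius(area: float) -> float:
    """Radius of the disk with the same area: r = sqrt(area / pi)."""
    if area <= 0:
        raise ValueError("area must be strictly positive")
    return float(np.sqrt(area / np.pi))


def normalized_barycenter_distance(s1: Mask2D, s2: Mask2D, radius_from: str = "s1") -> float:
    """d(b1, b2) / r with r the pseudo-radius of s1 (or s2 on request)."""
    _check_same_size(s1, s2)
    if radius_from not in ("s1", "s2"):
        raise ValueError("radius_from must be 's1' or 's2'")
    d = float(np.linalg.norm(barycenter(s1) - barycenter(s2)))
    r = pseudo_radius((s1 if radius_from == "s1" else s2).area)
    return d / r


def coverage_rate(s1: Mask2D, s2: Mask2D) -> float:
    """|s1 ∩ s2| / |s2|."""
    _check_same_size(s1, s2)
    denom = s2.area
    if denom == 0:
        raise ValueError("ground-truth mask s2 is empty")
    return float(np.logical_and(s1.data, s2.data).sum() / denom)


@dataclass
class OverlayReport:
    """Per-SLN overlay accuracy record.

    ``ratio`` uses the pseudo-radius of the AR surface s1 (primary);
    ``ratio_r_from_s2`` is the variant normalized by s2's pseudo-radius,
    reported alongside because both normalizations are defensible.
    """

    side: str
    area_s1: int
    area_s2: int
    b1: List[float]
    b2: List[float]
    d: float
    r: float
    ratio: float
    ratio_r_from_s2: float
    coverage: float

    def as_dict(self) -> dict:
        return asdict(self)


def overlay_report(side: str, s1: Mask2D, s2: Mask2D) -> OverlayReport:
    b1, b2 = barycenter(s1), barycenter(s2)
    d = float(np.linalg.norm(b1 - b2))
    r = pseudo_radius(s1.area)
    return OverlayReport(
        side=side,
        area_s1=s1.area,
        area_s2=s2.area,
        b1=b1.tolist(),
        b2=b2.tolist(),
        d=d,
        r=r,
        ratio=d / r,
        ratio_r_from_s2=d / pseudo_radius(s2.area),
        coverage=coverage_rate(s1, s2),
    )


def reports_to_frame(reports: Iterable[OverlayReport]) -> pd.DataFrame:
    """One row per SLN, for CSV export."""
    rows = []
    for rep in reports:
        row = rep.as_dict()
        row["b1_u"], row["b1_v"] = row.pop("b1")
        row["b2_u"], row["b2_v"] = row.pop("b2")
        rows.append(row)
    return pd.DataFrame(rows)
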