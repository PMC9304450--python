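"""Centerline-based geometric biomarkers.

Actual length (arc length of the centroid polyline), geometric length
(endpoint-to-endpoint chord), the tortuosity index
``ATI = (AL/GL - 1) * 100``, maximum fitted diameter, and a simple
mask-stack-to-centerline extractor for synthetic axial image stacks.
All lengths in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Centerline",
    "MaskStack",
    "actual_length",
    "geometric_length",
    "tortuosity_index",
    "max_diameter",
    "centerline_from_masks",
    "smooth_centerline",
]

logger = logging.getLogger(__name__)

#: GL below this fraction of AL triggers the degenerate-geometry error.
_GL_TOL_MM = 1e-6


@dataclass
class Centerline:
    """Ordered centroid points with per-point diameters (mm)."""

    points: np.ndarray            # (n, 3)
    diameters: np.ndarray         # (n,)
    regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        n = len(self.points)
        if n < 2:
            raise ValueError("centerline needs at least 2 points")
        if len(self.diameters) != n:
            raise ValueError("one diameter per point required")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.regions is not None:
            self.regions = np.asarray(self.regions, dtype=object)
            if len(self.regions) != n:
                raise ValueError("one region label per point required")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MaskStack:
    """Ordered binary axial slices with physical spacing.

    ``data`` has shape (n_slices, ny, nx); pixel centers sit at
    ``index * spacing`` (0-based voxel indices).
    """

    data: np.ndarray
    pixel_size_mm: float
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_slices, ny, nx)")
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be positive")


def actual_length(cl: Centerline) -> float:
    """Arc length following the centroid polyline (sum of segment lengths)."""
    seg = np.diff(cl.points, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def geometric_length(cl: Centerline) -> float:
    """Straight-line distance between the first and last centroid."""
    gl = float(np.linalg.norm(cl.points[-1] - cl.points[0]))
    if gl < _GL_TOL_MM * max(1.0, actual_length(cl)):
        logger.warning("near-closed centerline: GL=%.3g mm", gl)
    return gl


def tortuosity_index(cl: Centerline) -> float:
    """Tortuosity index ``(AL/GL - 1) * 100`` (dimensionless percent)."""
    al = actual_length(cl)
    gl = geometric_length(cl)
    if gl < _GL_TOL_MM * max(1.0, al):
        raise ValueError(f"degenerate geometry: GL={gl:.3g} mm")
    return (al / gl - 1.0) * 100.0


def max_diameter(cl: Centerline) -> float:
    """Maximum of the per-point fitted diameters (mm)."""
    return float(np.max(cl.diameters))


def smooth_centerline(cl: Centerline, k: int = 3) -> Centerline:
    """Moving-average smoothing over ``k`` points (k odd; endpoints kept)."""
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if k == 1:
        return cl
    half = k // 2
    pts = cl.points.copy()
    n = len(cl)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        pts[i] = cl.points[lo:hi].mean(axis=0)
    return Centerline(pts, cl.diameters.copy(),
                      None if cl.regions is None else cl.regions.copy())


def centerline_from_masks(stack: MaskStack) -> Centerline:
    """Extract a centerline from a binary axial stack.

    Each non-empty slice contributes its foreground centroid (voxel-center
    coordinates in mm) and an equivalent-area diameter
    ``2 * sqrt(area / pi)``.  Empty slices are skipped with a logged gap.
    """
    px = stack.pixel_size_mm
    dz = stack.slice_thickness_mm
    points = []
    diams = []
    n_empty = 0
    for iz, sl in enumerate(stack.data):
        ys, xs = np.nonzero(sl)
        if len(xs) == 0:
            n_empty += 1
            continue
        cx = xs.mean() * px
        cy = ys.mean() * px
        area = len(xs) * px * px
        points.append((cx, cy, iz * dz))
        diams.append(2.0 * np.sqrt(area / np.pi))
    if n_empty:
        logger.info("skipped %d empty slice(s)", n_empty)
    if len(points) < 2:
        raise ValueError("need at least 2 non-empty slices")
    return Centerline(np.asarray(points), np.asarray(diams))
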