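"""Compartment geometry, shrinkage estimation, biofilm thickness.

The wall-to-wall reference image of each section is measured like the
physical carrier compartment: side and diagonal lengths of the best-fitting
bounding square, compared against the carrier dimensions to estimate
shrinkage introduced by cryosectioning and hybridization, and biofilm
thickness read off at the midpoint of each side (along the inward normal)
and at each corner (along the inward diagonal) — eight measurements per
section.  Narrow biofilm channels (pores) crossing a measurement ray are
skipped, mirroring how an operator ignores obvious channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Polygon

from .imaging import BinaryMask

__all__ = [
    "CompartmentGeometry",
    "ThicknessMeasurements",
    "ShrinkageResult",
    "measure_compartment",
    "estimate_shrinkage",
    "measure_thickness",
]


@dataclass
class CompartmentGeometry:
    """Minimal-area bounding quadrilateral of the compartment footprint."""

    side_lengths_um: tuple[float, float, float, float]
    diagonals_um: tuple[float, float]
    area_um2: float
    depth_um: float = 0.0
    corners_px: np.ndarray | None = None  # 4x2 (row, col) vertices, pixel units

    @property
    def mean_side_um(self) -> float:
        return float(np.mean(self.side_lengths_um))


@dataclass
class ThicknessMeasurements:
    """Eight biofilm thickness readings: four side-normal, four corner-diagonal."""

    sides_um: tuple[float, float, float, float]
    corners_um: tuple[float, float, float, float]
    flagged: tuple[str, ...] = ()

    @property
    def side_mean_um(self) -> float:
        return float(np.mean(self.sides_um))

    @property
    def side_sd_um(self) -> float:
        return float(np.std(self.sides_um, ddof=1))

    @property
    def corner_mean_um(self) -> float:
        return float(np.mean(self.corners_um))

    @property
    def corner_sd_um(self) -> float:
        return float(np.std(self.corners_um, ddof=1))


@dataclass
class ShrinkageResult:
    linear_ratio: float
    area_ratio: float
    depth_um: float = 0.0


def measure_compartment(reference: BinaryMask, depth_um: float = 0.0) -> CompartmentGeometry:
    """Fit the minimal-area bounding quadrilateral of the footprint.

    The convex hull of the foreground is computed on pixel *corners* (pixel
    centers inflated by ±0.5 px) so an axis-aligned 600-px square measures
    exactly 600 px per side.  Degenerate (line-like) masks raise.
    """
    pts = np.argwhere(reference.data)
    if pts.size == 0:
        raise ValueError("reference mask is empty")
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        raise ValueError("degenerate (line-like) mask; no bounding quadrilateral")
    verts = pts[hull.vertices].astype(float)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (verts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    rect = MultiPoint([tuple(p) for p in corners]).minimum_rotated_rectangle
    if not isinstance(rect, Polygon):
        raise ValueError("degenerate (line-like) mask; no bounding quadrilateral")
    quad = np.asarray(rect.exterior.coords)[:4]
    px = reference.pixel_size_um
    sides = tuple(
        float(np.linalg.norm(quad[(i + 1) % 4] - quad[i]) * px) for i in range(4)
    )
    diagonals = (
        float(np.linalg.norm(quad[2] - quad[0]) * px),
        float(np.linalg.norm(quad[3] - quad[1]) * px),
    )
    return CompartmentGeometry(
        side_lengths_um=sides,
        diagonals_um=diagonals,
        area_um2=float(rect.area) * px**2,
        depth_um=depth_um,
        corners_px=quad,
    )


def estimate_shrinkage(
    measured: CompartmentGeometry,
    reference_side_um: float,
    reference_area_um2: float | None = None,
) -> ShrinkageResult:
    """Shrinkage ratios of a measured section against carrier dimensions.

    ``reference_side_um`` (and optionally ``reference_area_um2``) are the
    physical carrier-compartment dimensions at the matching depth; the
    carrier narrows toward its mid-depth "waist", so reference dimensions are
    per depth.  Ratios of 1.0 mean no shrinkage.
    """
    if not reference_side_um > 0:
        raise ValueError("reference_side_um must be > 0")
    if reference_area_um2 is None:
        reference_area_um2 = reference_side_um**2
    if not reference_area_um2 > 0:
        raise ValueError("reference_area_um2 must be > 0")
    return ShrinkageResult(
        linear_ratio=measured.mean_side_um / reference_side_um,
        area_ratio=measured.area_um2 / reference_area_um2,
        depth_um=measured.depth_um,
    )


def _ray_thickness(
    mask: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    max_len_px: float,
    pixel_size_um: float,
    channel_gap_um: float,
    step_px: float = 0.5,
) -> float:
    """Extent of contiguous foreground from the wall along a ray.

    Walks inward from ``start`` sampling the mask at ``step_px`` spacing;
    gaps shorter than ``channel_gap_um`` (biofilm channels) are skipped, a
    longer gap ends the measurement.
    """
    n_steps = int(max_len_px / step_px)
    t = np.arange(n_steps + 1) * step_px
    pos = start[None, :] + t[:, None] * direction[None, :]
    rr = np.clip(np.rint(pos[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.rint(pos[:, 1]).astype(int), 0, mask.shape[1] - 1)
    samples = mask[rr, cc]
    gap_steps = channel_gap_um / pixel_size_um / step_px
    thickness_px = 0.0
    gap_run = 0.0
    for i, fg in enumerate(samples):
        if fg:
            thickness_px = t[i]
            gap_run = 0.0
        else:
            gap_run += step_px
            if gap_run >= gap_steps * step_px:
                break
    return thickness_px * pixel_size_um


def measure_thickness(
    reference: BinaryMask,
    channel_gap_um: float = 10.0,
    geometry: CompartmentGeometry | None = None,
) -> ThicknessMeasurements:
    """Eight thickness measurements of a wall-attached biofilm band.

    At the midpoint of each compartment side the thickness is measured along
    the inward normal; at each corner, along the inward diagonal.  The
    measurement is the extent of contiguous foreground from the wall; gaps
    narrower than ``channel_gap_um`` are treated as biofilm channels and
    skipped.  Side rays are capped at half the compartment width and corner
    rays at half the diagonal (a full compartment measures side/2).  Rays
    hitting no foreground at the wall report 0 and are flagged.
    """
    mask = reference.data
    if not mask.any():
        raise ValueError("reference mask is empty")
    if geometry is None:
        geometry = measure_compartment(reference)
    quad = geometry.corners_px
    center = quad.mean(axis=0)
    px = reference.pixel_size_um

    sides = []
    corners = []
    flagged = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        mid = (a + b) / 2
        normal = center - mid
        length = np.linalg.norm(normal)
        direction = normal / length
        t = _ray_thickness(mask, mid, direction, length, px, channel_gap_um)
        sides.append(t)
        if t == 0.0:
            flagged.append(f"side_{i}")
    for i in range(4):
        diag = center - quad[i]
        length = np.linalg.norm(diag)
        direction = diag / length
        t = _ray_thickness(mask, quad[i], direction, length, px, channel_gap_um)
        corners.append(t)
        if t == 0.0:
            flagged.append(f"corner_{i}")
    half_diag = float(np.linalg.norm(quad[2] - quad[0]) / 2) * px
    for v in sides + corners:
        if v > half_diag * (1 + 1e-6):
            raise ValueError("thickness exceeds half the compartment diagonal")
    return ThicknessMeasurements(
        sides_um=tuple(sides), corners_um=tuple(corners), flagged=tuple(flagged)
    )
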