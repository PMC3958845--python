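"""Object segmentation, congruency scoring, artifact rejection, biovolume.

Probe-labeled biomass in a thresholded channel is segmented into 8-connected
objects (microcolonies).  Each object's *congruency* is the fraction of its
area lying inside the reference-channel ("all bacteria") mask; genuine cells
hybridize with the reference probe mix too, so low-congruency objects are
imaging artifacts.  Autofluorescent material additionally shows up with the
same footprint in both specific channels and is removed by a dual-channel
overlap rule before congruency filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import BinaryMask

__all__ = [
    "SegmentedObject",
    "ArtifactParams",
    "segment",
    "congruency",
    "score_congruency",
    "remove_autofluorescent",
    "reject_artifacts",
    "biovolume_fraction",
    "areal_density",
    "objects_to_mask",
    "object_table",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(eq=False)
class SegmentedObject:
    """One 8-connected foreground component of a binary mask."""

    object_id: int
    pixel_index: np.ndarray  # flat indices into the source grid
    grid_shape: tuple[int, int]
    pixel_size_um: float
    channel: str = ""
    congruency: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_index.size < 1:
            raise ValueError("object must contain at least one pixel")

    @property
    def area_px(self) -> int:
        return int(self.pixel_index.size)

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


@dataclass
class ArtifactParams:
    """Congruency thresholds for artifact rejection.

    ``object_congruency_threshold``: objects whose congruency with the
    reference falls below this are dropped (default 50%).
    ``aggregate_congruency_requirement``: after filtering, the area-weighted
    congruency of everything kept must reach this (default 90%) for the image
    to pass QC.
    """

    object_congruency_threshold: float = 0.50
    aggregate_congruency_requirement: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.object_congruency_threshold, self.aggregate_congruency_requirement):
            if not 0.0 <= v <= 1.0:
                raise ValueError("congruency thresholds must lie in [0, 1]")


def segment(mask: BinaryMask, channel: str = "") -> list[SegmentedObject]:
    """Segment a binary mask into maximal 8-connected objects.

    Every foreground pixel belongs to exactly one object; an empty mask
    yields an empty list.
    """
    labels, n = ndimage.label(mask.data, structure=_EIGHT)
    if n == 0:
        return []
    flat_idx = np.flatnonzero(labels)
    vals = labels.ravel()[flat_idx]
    order = np.argsort(vals, kind="stable")
    flat_idx = flat_idx[order]
    vals = vals[order]
    bounds = np.searchsorted(vals, np.arange(1, n + 2))
    out = []
    for i in range(n):
        out.append(
            SegmentedObject(
                object_id=i + 1,
                pixel_index=flat_idx[bounds[i] : bounds[i + 1]],
                grid_shape=mask.data.shape,
                pixel_size_um=mask.pixel_size_um,
                channel=channel,
            )
        )
    return out


def congruency(obj: SegmentedObject, reference: BinaryMask) -> float:
    """Fraction of the object's pixels lying inside the reference mask."""
    if obj.grid_shape != reference.data.shape:
        raise ValueError("object and reference are on different grids")
    return float(reference.data.ravel()[obj.pixel_index].mean())


def score_congruency(
    objects: list[SegmentedObject], reference: BinaryMask
) -> list[SegmentedObject]:
    """Set ``congruency`` on every object (in place); returns the list."""
    for obj in objects:
        obj.congruency = congruency(obj, reference)
    return objects


def objects_to_mask(
    objects: list[SegmentedObject],
    grid_shape: tuple[int, int] | None = None,
    pixel_size_um: float | None = None,
) -> BinaryMask:
    """Union of the objects' pixels as a binary mask."""
    if not objects:
        if grid_shape is None or pixel_size_um is None:
            raise ValueError("grid_shape and pixel_size_um required for empty list")
        return BinaryMask(np.zeros(grid_shape, dtype=bool), pixel_size_um)
    shape = objects[0].grid_shape
    out = np.zeros(shape[0] * shape[1], dtype=bool)
    for obj in objects:
        out[obj.pixel_index] = True
    return BinaryMask(out.reshape(shape), objects[0].pixel_size_um)


def remove_autofluorescent(
    objects_a: list[SegmentedObject],
    objects_b: list[SegmentedObject],
    overlap_rule: float = 0.50,
) -> tuple[list[SegmentedObject], list[SegmentedObject], list[SegmentedObject]]:
    """Remove objects present in both specific channels.

    An object in channel A is removed iff at least ``overlap_rule`` of its
    own area overlaps channel B's foreground, and symmetrically.  Both
    directions are evaluated against the *input* masks, so removal is
    order-independent.  Returns (filtered_a, filtered_b, removed).
    """
    if not 0.0 < overlap_rule <= 1.0:
        raise ValueError("overlap_rule must lie in (0, 1]")
    removed: list[SegmentedObject] = []

    def _filter(objs, other_objs):
        if not objs:
            return []
        shape = objs[0].grid_shape
        other = np.zeros(shape[0] * shape[1], dtype=bool)
        for o in other_objs:
            if o.grid_shape != shape:
                raise ValueError("object lists are on different grids")
            other[o.pixel_index] = True
        kept = []
        for o in objs:
            frac = float(other[o.pixel_index].mean())
            if frac >= overlap_rule:
                removed.append(o)
            else:
                kept.append(o)
        return kept

    return _filter(objects_a, objects_b), _filter(objects_b, objects_a), removed


def reject_artifacts(
    objects: list[SegmentedObject],
    reference: BinaryMask,
    params: ArtifactParams | None = None,
) -> tuple[list[SegmentedObject], bool]:
    """Congruency-based artifact rejection with an aggregate QC gate.

    Objects whose congruency with the reference is below
    ``object_congruency_threshold`` are dropped.  The image passes QC iff the
    area-weighted congruency of the kept objects reaches
    ``aggregate_congruency_requirement``; failing images are flagged (flag
    False), never silently dropped.  An empty object list passes vacuously.
    """
    params = params or ArtifactParams()
    objects = [
        o if o.congruency is not None else score_congruency([o], reference)[0]
        for o in objects
    ]
    kept = [o for o in objects if o.congruency >= params.object_congruency_threshold]
    total = sum(o.area_px for o in kept)
    if total == 0:
        return kept, True
    inside = sum(o.area_px * o.congruency for o in kept)
    passed = inside / total >= params.aggregate_congruency_requirement
    return kept, passed


def biovolume_fraction(
    kept_objects: list[SegmentedObject], reference: BinaryMask
) -> float:
    """Biovolume fraction: kept specific-probe area over reference area.

    A value above 1 is a contract violation (it means congruency filtering
    was skipped) and raises rather than being clamped.
    """
    ref_area = reference.area_px
    if ref_area == 0:
        raise ValueError("reference mask is empty; biovolume fraction undefined")
    total = sum(o.area_px for o in kept_objects)
    frac = total / ref_area
    if frac > 1.0:
        raise ValueError(
            f"biovolume fraction {frac:.3f} > 1; congruency filtering was skipped?"
        )
    return frac


def areal_density(reference: BinaryMask, compartment_area_um2: float) -> float:
    """Biomass areal density: reference signal area over compartment area."""
    if not compartment_area_um2 > 0:
        raise ValueError("compartment_area_um2 must be > 0")
    area = reference.area_um2
    if area > compartment_area_um2 * (1 + 1e-9):
        raise ValueError(
            f"reference area {area:.1f} um^2 exceeds compartment area "
            f"{compartment_area_um2:.1f} um^2"
        )
    return min(area / compartment_area_um2, 1.0)


def object_table(
    objects: list[SegmentedObject], removed_reason: str = ""
) -> pd.DataFrame:
    """Tabulate objects for CSV export."""
    return pd.DataFrame(
        {
            "object_id": [o.object_id for o in objects],
            "channel": [o.channel for o in objects],
            "area_px": [o.area_px for o in objects],
            "area_um2": [o.area_um2 for o in objects],
            "congruency": [o.congruency for o in objects],
            "removed_reason": removed_reason,
        }
    )
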