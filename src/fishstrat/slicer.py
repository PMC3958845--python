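"""Multidirectional wall-distance stratification ("slicer").

To quantify horizontal (x, y) stratification inside a square carrier
compartment, every pixel of the wall-to-wall compartment footprint is
labeled by its Euclidean distance to the compartment wall, binned into
concentric virtual slices (default 100 µm thick).  Per-slice biovolume
fractions are then averaged across sections with t-based 95% confidence
intervals, exactly mirroring how concentric-shell profiles are reported for
biofilm micrographs.

Conventions
-----------
* The region outside the image grid counts as background, so a footprint
  that fills the grid still has a well-defined wall.
* Wall distance of a pixel is measured from its center to the wall:
  EDT − 0.5 px.  A 1000 µm square at 1 µm/px therefore yields exactly five
  100 µm shells, the innermost a 200 px square.
* "Baseline smoothing" smooths the compartment boundary contour with a
  circular moving average whose window spans the given fraction of a
  compartment side before distances are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import draw, measure

from .imaging import BinaryMask
from .objects import SegmentedObject

__all__ = [
    "SlicerParams",
    "ShellProfile",
    "wall_distance_shells",
    "wall_distance_map",
    "shell_biovolume_profile",
    "aggregate_shell_profiles",
    "profiles_to_frame",
]


@dataclass
class SlicerParams:
    slice_thickness_um: float = 100.0
    baseline_smoothing_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.slice_thickness_um > 0:
            raise ValueError("slice_thickness_um must be > 0")
        if not 0.0 <= self.baseline_smoothing_fraction < 1.0:
            raise ValueError("baseline_smoothing_fraction must lie in [0, 1)")


@dataclass
class ShellProfile:
    """Per-shell biovolume fractions for one section.

    ``fractions`` maps probe name to specific-area / reference-area within
    the shell; a probe maps to NaN when the shell holds no reference signal
    (missing, not zero).
    """

    shell_index: int
    d_lo_um: float
    d_hi_um: float
    shell_area_um2: float
    fractions: dict[str, float]
    reference_area_px: int
    n_sections: int = 1


def _smoothed_footprint(mask: np.ndarray, smoothing_fraction: float) -> np.ndarray:
    """Rasterize the boundary contour smoothed by a circular moving average."""
    padded = np.pad(mask, 1, constant_values=False)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    n = len(contour)
    side_pts = n / 4.0  # perimeter points per compartment side
    window = max(int(round(smoothing_fraction * side_pts)), 1)
    if window > 1:
        sm = np.empty_like(contour)
        for k in (0, 1):
            sm[:, k] = ndimage.uniform_filter1d(contour[:, k], size=window, mode="wrap")
        contour = sm
    rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=mask.shape)
    out = np.zeros_like(mask, dtype=bool)
    out[rr, cc] = True
    return out


def wall_distance_map(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Pixel-center distance (µm) to the nearest background pixel.

    The grid is padded with one background ring so the image border acts as
    a wall; distances are EDT − 0.5 px, clipped at 0, and NaN outside the
    mask.
    """
    padded = np.pad(mask, 1, constant_values=False)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    d = np.clip(edt - 0.5, 0.0, None) * pixel_size_um
    d[~mask] = np.nan
    return d


def wall_distance_shells(
    compartment_mask: BinaryMask, params: SlicerParams | None = None
) -> np.ndarray:
    """Label every footprint pixel with its virtual-slice (shell) index.

    Returns an integer grid: ``floor(wall distance / slice thickness)``
    inside the compartment footprint, −1 outside.  The labels partition the
    footprint; the innermost shell may be thinner than the nominal
    thickness.  The footprint must be one simply connected region.
    """
    params = params or SlicerParams()
    mask = compartment_mask.data
    if not mask.any():
        raise ValueError("compartment mask is empty")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(
            f"compartment mask must be simply connected; found {n_comp} components"
        )
    if (ndimage.binary_fill_holes(mask) != mask).any():
        raise ValueError("compartment mask must be simply connected; it has holes")

    base = mask
    if params.baseline_smoothing_fraction > 0:
        base = _smoothed_footprint(mask, params.baseline_smoothing_fraction)
    d = wall_distance_map(base, compartment_mask.pixel_size_um)
    labels = np.full(mask.shape, -1, dtype=np.int32)
    inside_base = mask & base
    labels[inside_base] = np.floor(
        d[inside_base] / params.slice_thickness_um
    ).astype(np.int32)
    # footprint pixels shaved off by the smoothed baseline belong to shell 0
    labels[mask & ~base] = 0
    return labels


def shell_biovolume_profile(
    shells: np.ndarray,
    kept_objects_per_probe: dict[str, list[SegmentedObject]],
    reference: BinaryMask,
    params: SlicerParams | None = None,
) -> list[ShellProfile]:
    """Per-shell biovolume fraction of each probe for one section.

    Fraction = kept specific-probe area within the shell / reference area
    within the shell.  Shells without reference signal are reported with NaN
    fractions (missing), never as zero.
    """
    params = params or SlicerParams()
    if shells.shape != reference.data.shape:
        raise ValueError("shells and reference are on different grids")
    n_shells = int(shells.max()) + 1
    if n_shells <= 0:
        raise ValueError("shell grid contains no shells")
    px2 = reference.pixel_size_um**2
    shell_flat = shells.ravel()
    valid = shell_flat >= 0
    shell_areas = np.bincount(shell_flat[valid], minlength=n_shells)
    ref_counts = np.bincount(
        shell_flat[valid & reference.data.ravel()], minlength=n_shells
    )
    probe_counts = {}
    for probe, objs in kept_objects_per_probe.items():
        counts = np.zeros(n_shells, dtype=np.int64)
        for o in objs:
            lab = shell_flat[o.pixel_index]
            counts += np.bincount(lab[lab >= 0], minlength=n_shells)
        probe_counts[probe] = counts

    thickness = params.slice_thickness_um
    out = []
    for s in range(n_shells):
        fractions = {}
        for probe, counts in probe_counts.items():
            if ref_counts[s] == 0:
                fractions[probe] = float("nan")
            else:
                fractions[probe] = counts[s] / ref_counts[s]
        out.append(
            ShellProfile(
                shell_index=s,
                d_lo_um=s * thickness,
                d_hi_um=(s + 1) * thickness,
                shell_area_um2=float(shell_areas[s]) * px2,
                fractions=fractions,
                reference_area_px=int(ref_counts[s]),
            )
        )
    return out


def profiles_to_frame(
    profiles_per_section: list[list[ShellProfile]],
) -> pd.DataFrame:
    """Long-form table (section, shell, probe, fraction) from per-section profiles."""
    rows = []
    for sec, profiles in enumerate(profiles_per_section):
        for p in profiles:
            for probe, frac in p.fractions.items():
                rows.append(
                    {
                        "section": sec,
                        "shell_index": p.shell_index,
                        "shell_lo_um": p.d_lo_um,
                        "shell_hi_um": p.d_hi_um,
                        "probe": probe,
                        "fraction": frac,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_shell_profiles(
    profiles_per_section: list[list[ShellProfile]] | pd.DataFrame,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Average per-shell fractions across sections with t-based CIs.

    Missing shells (NaN fraction, or a section that never reaches the deep
    shell) are excluded, so n may shrink for inner shells.  With n = 1 the
    mean is reported and the CI is NaN, flagged in ``ci_defined``.
    """
    if isinstance(profiles_per_section, pd.DataFrame):
        frame = profiles_per_section
    else:
        frame = profiles_to_frame(profiles_per_section)
    rows = []
    for (shell, probe), grp in frame.groupby(["shell_index", "probe"], sort=True):
        vals = grp["fraction"].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            continue
        mean = float(vals.mean())
        if n >= 2:
            sem = vals.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
            defined = True
        else:
            lo = hi = float("nan")
            defined = False
        rows.append(
            {
                "shell_index": shell,
                "shell_lo_um": float(grp["shell_lo_um"].iloc[0]),
                "shell_hi_um": float(grp["shell_hi_um"].iloc[0]),
                "probe": probe,
                "mean_fraction": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "n": n,
                "ci_defined": defined,
            }
        )
    return pd.DataFrame(rows)
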