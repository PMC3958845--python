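"""Synthetic FISH-section generator with exact ground truth.

Emulates multi-channel cryosection micrographs of a square (~1 mm) MBBR
carrier compartment colonized by nitritation-anammox biofilm: microcolonies
rendered as blurred discs, an ammonia-oxidizer (AOB) population whose share
of the biomass falls with section depth z and toward the compartment walls,
an anammox population rising with z (to ~400 µm) and toward the walls,
biomass thicker in the corners than on the sides, autofluorescent objects
that appear with identical footprints in both specific probe channels, and
isolated-pixel speckle noise.  Every stack comes with pixel-exact ground
truth, so each downstream stage of the quantification pipeline can be
verified against known class masks and fractions.

Profile semantics
-----------------
``aob_profile(z, d)`` and ``amx_profile(z, d)`` are target *biovolume
fractions* — the share of the reference ("all bacteria") biomass belonging
to each guild at depth z (µm) and wall distance d (µm).  The remaining share
(1 − aob − amx) is rendered as unlabeled "other" bacteria, so measured
fractions equal the configured targets.  ``biomass_density(z)`` sets the
areal density of the reference biomass itself (signal area over compartment
area).  Profile callables should accept numpy arrays for ``d``; scalar-only
callables are wrapped automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw

from .imaging import (
    AMX_CHANNEL,
    AOB_CHANNEL,
    REFERENCE_CHANNEL,
    BinaryMask,
    SectionImage,
    write_labels,
    write_section,
)
from .slicer import SlicerParams, wall_distance_map, wall_distance_shells

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_compartment_stack",
    "expected_profile",
    "plant_artifacts",
    "wall_band_mask",
    "expected_colony_count",
    "save_stack",
]

LABEL_BACKGROUND = 0
LABEL_AOB = 1
LABEL_AMX = 2
LABEL_OTHER = 3
LABEL_ARTIFACT = 4

CLASS_NAMES = {
    LABEL_AOB: "aob",
    LABEL_AMX: "amx",
    LABEL_OTHER: "other",
    LABEL_ARTIFACT: "artifact",
}
CLASS_CHANNELS = {LABEL_AOB: AOB_CHANNEL, LABEL_AMX: AMX_CHANNEL}


def default_aob_profile(z: float, d) -> np.ndarray:
    """AOB biovolume fraction: 0.40 → 0.05 over 0–800 µm depth, lower near walls."""
    base = 0.40 - 0.35 * min(float(z), 800.0) / 800.0
    mod = 0.10 * (np.minimum(np.asarray(d, dtype=float), 500.0) / 500.0 - 0.5)
    return np.clip(base + mod, 0.0, 1.0)


def default_amx_profile(z: float, d) -> np.ndarray:
    """Anammox fraction: 0 → 0.30 over 180–400 µm depth, higher near walls."""
    base = 0.30 * min(max((float(z) - 180.0) / 220.0, 0.0), 1.0)
    mod = 0.10 * (0.5 - np.minimum(np.asarray(d, dtype=float), 500.0) / 500.0)
    return np.clip(base + mod, 0.0, 1.0)


def default_biomass_density(z: float) -> float:
    """Reference areal density rising with depth down to 400 µm, then flat."""
    return 0.20 + 0.15 * min(max(float(z), 0.0) / 400.0, 1.0)


def _eval_profile(profile: Callable, z: float, d: np.ndarray) -> np.ndarray:
    """Evaluate a (z, d)->fraction profile, tolerating scalar-only callables."""
    try:
        out = np.asarray(profile(z, d), dtype=float)
        if out.shape != np.shape(d):
            out = np.broadcast_to(out, np.shape(d)).copy()
        return out
    except (TypeError, ValueError):
        return np.vectorize(lambda dd: float(profile(z, dd)))(d)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic compartment stack.

    Defaults render the mature-biofilm study conditions: a 1 mm compartment
    imaged at 2 µm/px, 41 sections from 0 to 800 µm depth, AOB declining and
    anammox rising with depth, mild wall-distance modulation of both, and a
    corner/side biomass-thickness ratio of 336/235 when a wall band is
    rendered.
    """

    grid_size_px: int = 500
    pixel_size_um: float = 2.0
    section_depths_um: tuple[float, ...] = tuple(range(0, 801, 20))
    compartment_side_um: float = 1000.0
    aob_profile: Callable = default_aob_profile
    amx_profile: Callable = default_amx_profile
    other_bacteria_fraction: Callable[[float], float] | None = None
    biomass_density: Callable[[float], float] = default_biomass_density
    colony_radius_um: tuple[float, float] = (8.0, 3.0)  # mean, sd
    corner_thickening_factor: float = 336.0 / 235.0
    band_thickness_um: float | None = None  # None: colonies across the whole footprint
    artifact_rate: float = 0.0  # expected autofluorescent objects per section
    artifact_radius_um: tuple[float, float] = (6.0, 2.0)
    speckle_rate: float = 0.0  # isolated foreground pixels per 1e4 pixels
    foreground_intensity: tuple[float, float] = (180.0, 30.0)  # mean, sd (8-bit)
    background_intensity: tuple[float, float] = (10.0, 3.0)
    edge_blur_sigma_px: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size_px * self.pixel_size_um < self.compartment_side_um - 1e-9:
            raise ValueError(
                "grid_size_px x pixel_size_um must cover compartment_side_um"
            )
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.speckle_rate < 0:
            raise ValueError("speckle_rate must be >= 0")
        if self.corner_thickening_factor < 1:
            raise ValueError("corner_thickening_factor must be >= 1")

    # -- geometry helpers -------------------------------------------------

    @property
    def side_px(self) -> int:
        return int(round(self.compartment_side_um / self.pixel_size_um))

    def footprint(self) -> np.ndarray:
        """Boolean compartment footprint centered on the grid."""
        g = self.grid_size_px
        s = self.side_px
        off = (g - s) // 2
        out = np.zeros((g, g), dtype=bool)
        out[off : off + s, off : off + s] = True
        return out

    def wall_distance(self) -> np.ndarray:
        """Wall distance (µm) of every footprint pixel; NaN outside."""
        return wall_distance_map(self.footprint(), self.pixel_size_um)

    def support(self) -> np.ndarray:
        """Region colonies may occupy: wall band if configured, else footprint."""
        foot = self.footprint()
        if self.band_thickness_um is None:
            return foot
        return wall_band_mask(
            foot,
            self.pixel_size_um,
            self.band_thickness_um,
            self.band_thickness_um * self.corner_thickening_factor,
        )

    def validate_profiles(self) -> None:
        """Check all target fractions are in [0, 1] and sum <= 1 everywhere."""
        d = self.wall_distance()
        dd = d[np.isfinite(d)]
        for z in self.section_depths_um:
            a = _eval_profile(self.aob_profile, z, dd)
            m = _eval_profile(self.amx_profile, z, dd)
            other = (
                float(self.other_bacteria_fraction(z))
                if self.other_bacteria_fraction is not None
                else 0.0
            )
            total = a + m + other
            bad = (a < 0) | (a > 1) | (m < 0) | (m > 1) | (total > 1 + 1e-9)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"inconsistent fraction profiles at z={z} um, "
                    f"wall_distance={dd[i]:.1f} um: aob={a.flat[i]:.3f}, "
                    f"amx={m.flat[i]:.3f}, other>={other:.3f} (sum > 1 or out of [0,1])"
                )


def wall_band_mask(
    footprint: np.ndarray,
    pixel_size_um: float,
    side_thickness_um: float,
    corner_thickness_um: float,
) -> np.ndarray:
    """Wall-attached band: uniform thickness on the sides, thicker corners.

    The band is the set of footprint pixels within ``side_thickness_um`` of
    the wall, unioned with quarter-discs of radius ``corner_thickness_um``
    at the four compartment corners, so the extent along each inward
    diagonal equals the corner thickness.
    """
    d = wall_distance_map(footprint, pixel_size_um)
    band = np.zeros_like(footprint)
    inside = np.isfinite(d)
    band[inside] = d[inside] <= side_thickness_um
    rows = np.any(footprint, axis=1).nonzero()[0]
    cols = np.any(footprint, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
    rr, cc = np.mgrid[0 : footprint.shape[0], 0 : footprint.shape[1]]
    rad_px = corner_thickness_um / pixel_size_um
    for cr, ccol in ((r0, c0), (r0, c1), (r1, c0), (r1, c1)):
        disc = (rr - cr) ** 2 + (cc - ccol) ** 2 <= rad_px**2
        band |= disc & footprint
    return band


def expected_colony_count(config: SyntheticConfig, z: float) -> float:
    """Expected number of colonies placed in the section at depth z.

    Colony discs are laid down with Poisson intensity chosen so the union
    covers the target areal density: coverage 1 − exp(−λ) = ρ.
    """
    rho = min(max(float(config.biomass_density(z)), 0.0), 0.999)
    if rho == 0:
        return 0.0
    lam = -math.log(1.0 - rho)
    mean_r = config.colony_radius_um[0]
    mean_area = math.pi * mean_r**2
    support_area = config.support().sum() * config.pixel_size_um**2
    return lam * support_area / mean_area


@dataclass
class GroundTruth:
    """Pixel-exact class labels and true fractions for a synthetic stack."""

    labels: list[np.ndarray]  # int8 grids: 0 bg, 1 AOB, 2 anammox, 3 other, 4 artifact
    depths_um: tuple[float, ...]
    pixel_size_um: float
    footprint: np.ndarray

    def class_mask(self, section: int, label: int) -> np.ndarray:
        return self.labels[section] == label

    def biomass_mask(self, section: int) -> np.ndarray:
        """Reference biomass: all bacterial classes, excluding artifacts."""
        lab = self.labels[section]
        return (lab >= LABEL_AOB) & (lab <= LABEL_OTHER)

    def artifact_mask(self, section: int) -> np.ndarray:
        return self.labels[section] == LABEL_ARTIFACT

    def depth_profile(self) -> pd.DataFrame:
        """True per-section biovolume fractions and areal density."""
        rows = []
        comp_px = int(self.footprint.sum())
        for k, z in enumerate(self.depths_um):
            biomass = self.biomass_mask(k)
            total = int(biomass.sum())
            for label in (LABEL_AOB, LABEL_AMX, LABEL_OTHER):
                n = int(self.class_mask(k, label).sum())
                rows.append(
                    {
                        "depth_um": z,
                        "probe": CLASS_NAMES[label],
                        "fraction": n / total if total else float("nan"),
                    }
                )
            rows.append(
                {
                    "depth_um": z,
                    "probe": "areal_density",
                    "fraction": total / comp_px,
                }
            )
        return pd.DataFrame(rows)

    def shell_profile(self, params: SlicerParams | None = None) -> pd.DataFrame:
        """True per-shell biovolume fractions, averaged over sections."""
        params = params or SlicerParams(baseline_smoothing_fraction=0.0)
        shells = wall_distance_shells(
            BinaryMask(self.footprint, self.pixel_size_um), params
        )
        flat = shells.ravel()
        n_shells = int(shells.max()) + 1
        rows = []
        for k, z in enumerate(self.depths_um):
            biomass = self.biomass_mask(k).ravel()
            ref = np.bincount(flat[(flat >= 0) & biomass], minlength=n_shells)
            for label in (LABEL_AOB, LABEL_AMX, LABEL_OTHER):
                cls = self.class_mask(k, label).ravel()
                cnt = np.bincount(flat[(flat >= 0) & cls], minlength=n_shells)
                for s in range(n_shells):
                    rows.append(
                        {
                            "depth_um": z,
                            "shell_index": s,
                            "probe": CLASS_NAMES[label],
                            "fraction": cnt[s] / ref[s] if ref[s] else float("nan"),
                        }
                    )
        return pd.DataFrame(rows)


def _render_channels(
    label: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    fg_mean, fg_sd = config.foreground_intensity
    bg_mean, bg_sd = config.background_intensity
    shape = label.shape
    fg_sets = {
        REFERENCE_CHANNEL: (label >= LABEL_AOB) & (label <= LABEL_OTHER),
        AOB_CHANNEL: (label == LABEL_AOB) | (label == LABEL_ARTIFACT),
        AMX_CHANNEL: (label == LABEL_AMX) | (label == LABEL_ARTIFACT),
    }
    channels = {}
    n_speckle = rng.poisson(config.speckle_rate * label.size / 1e4)
    for name, fg in fg_sets.items():
        img = rng.normal(bg_mean, bg_sd, shape)
        nfg = int(fg.sum())
        if nfg:
            img[fg] = rng.normal(fg_mean, fg_sd, nfg)
        if n_speckle:
            rr = rng.integers(0, shape[0], n_speckle)
            cc = rng.integers(0, shape[1], n_speckle)
            img[rr, cc] = rng.normal(fg_mean, fg_sd, n_speckle)
        if config.edge_blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, config.edge_blur_sigma_px)
        channels[name] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return channels


def _place_colonies(
    config: SyntheticConfig,
    z: float,
    d_map: np.ndarray,
    support: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lay down class-labeled colony discs; later discs overwrite earlier."""
    label = np.zeros(support.shape, dtype=np.int8)
    n = rng.poisson(expected_colony_count(config, z))
    if n == 0:
        return label
    support_idx = np.flatnonzero(support)
    centers = support_idx[rng.integers(0, support_idx.size, n)]
    crow, ccol = np.unravel_index(centers, support.shape)
    mean_r, sd_r = config.colony_radius_um
    radii_px = np.clip(
        rng.normal(mean_r, sd_r, n), 2.0, None
    ) / config.pixel_size_um
    d_at = d_map.ravel()[centers]
    d_at = np.nan_to_num(d_at, nan=0.0)
    p_aob = _eval_profile(config.aob_profile, z, d_at)
    p_amx = _eval_profile(config.amx_profile, z, d_at)
    u = rng.random(n)
    cls = np.full(n, LABEL_OTHER, dtype=np.int8)
    cls[u < p_aob] = LABEL_AOB
    cls[(u >= p_aob) & (u < p_aob + p_amx)] = LABEL_AMX
    for i in range(n):
        rr, cc = draw.disk((crow[i], ccol[i]), radii_px[i], shape=support.shape)
        label[rr, cc] = cls[i]
    # clip colonies to the support region
    label[~support] = LABEL_BACKGROUND
    return label


def plant_artifacts(
    image: SectionImage,
    rate: float,
    seed: int | np.random.Generator = 0,
    clearance_um: float = 6.0,
    radius_um: tuple[float, float] = (6.0, 2.0),
    biomass_mask: np.ndarray | None = None,
    intensity: tuple[float, float] = (180.0, 30.0),
) -> tuple[SectionImage, np.ndarray]:
    """Add autofluorescent objects to both specific channels.

    Planted objects have identical footprints in the AOB and anammox probe
    channels but are absent from the reference channel; the count is
    Poisson(``rate``).  Centers are placed at least ``clearance_um`` plus the
    object radius away from existing biomass (from ``biomass_mask`` when
    given, else from the thresholded reference channel) so artifacts do not
    merge with genuine colonies.  Returns the augmented image and the
    combined artifact footprint mask.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    for ch in (AOB_CHANNEL, AMX_CHANNEL):
        if ch not in image.channels:
            raise ValueError(f"image lacks specific channel {ch!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = image.shape
    artifact = np.zeros(shape, dtype=bool)
    n = rng.poisson(rate)
    if n == 0:
        return image, artifact
    if biomass_mask is None:
        biomass_mask = image.channel(REFERENCE_CHANNEL) >= 30
    clear_px = ndimage.distance_transform_edt(~biomass_mask)
    radii_px = np.clip(rng.normal(*radius_um, n), 2.0, None) / image.pixel_size_um
    for i in range(n):
        need = radii_px[i] + clearance_um / image.pixel_size_um
        ok = np.flatnonzero(clear_px.ravel() >= need)
        if ok.size == 0:
            continue
        center = ok[rng.integers(0, ok.size)]
        cr, cc = np.unravel_index(center, shape)
        rr, col = draw.disk((cr, cc), radii_px[i], shape=shape)
        artifact[rr, col] = True
    channels = {n_: ch.copy() for n_, ch in image.channels.items()}
    nfg = int(artifact.sum())
    for ch in (AOB_CHANNEL, AMX_CHANNEL):
        vals = np.clip(np.rint(rng.normal(*intensity, nfg)), 0, 255).astype(np.uint8)
        arr = channels[ch]
        arr[artifact] = np.maximum(arr[artifact], vals)
    out = SectionImage(
        channels=channels,
        pixel_size_um=image.pixel_size_um,
        depth_um=image.depth_um,
        compartment_id=image.compartment_id,
    )
    return out, artifact


def generate_compartment_stack(
    config: SyntheticConfig,
) -> tuple[list[SectionImage], GroundTruth]:
    """Render one synthetic compartment stack with ground truth.

    One image per entry of ``section_depths_um``.  The reference channel is
    the union of all bacterial colony pixels; the specific channels are
    subsets of the reference except for planted artifacts.  Fixed seed gives
    bit-identical output.
    """
    config.validate_profiles()
    foot = config.footprint()
    d_map = config.wall_distance()
    support = config.support()
    images = []
    labels = []
    for k, z in enumerate(config.section_depths_um):
        rng = np.random.default_rng([config.seed, k])
        label = _place_colonies(config, z, d_map, support, rng)
        # artifacts are planted on the label grid before intensity rendering
        if config.artifact_rate > 0:
            art = _plant_artifacts_on_labels(label, config, rng)
            label[art] = LABEL_ARTIFACT
        channels = _render_channels(label, config, rng)
        images.append(
            SectionImage(
                channels=channels,
                pixel_size_um=config.pixel_size_um,
                depth_um=float(z),
                compartment_id=f"synthetic-{config.seed}",
            )
        )
        labels.append(label)
    gt = GroundTruth(
        labels=labels,
        depths_um=tuple(float(z) for z in config.section_depths_um),
        pixel_size_um=config.pixel_size_um,
        footprint=foot,
    )
    return images, gt


def _plant_artifacts_on_labels(
    label: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Artifact footprints clear of existing biomass (label-grid variant)."""
    artifact = np.zeros(label.shape, dtype=bool)
    n = rng.poisson(config.artifact_rate)
    if n == 0:
        return artifact
    biomass = label > 0
    clear_px = ndimage.distance_transform_edt(~biomass)
    radii_px = np.clip(
        rng.normal(*config.artifact_radius_um, n), 2.0, None
    ) / config.pixel_size_um
    clearance_px = 6.0 / config.pixel_size_um
    for i in range(n):
        ok = np.flatnonzero(clear_px.ravel() >= radii_px[i] + clearance_px)
        if ok.size == 0:
            continue
        center = ok[rng.integers(0, ok.size)]
        cr, cc = np.unravel_index(center, label.shape)
        rr, col = draw.disk((cr, cc), radii_px[i], shape=label.shape)
        artifact[rr, col] = True
    return artifact


def expected_profile(
    config: SyntheticConfig, slicer_params: SlicerParams | None = None
) -> pd.DataFrame:
    """Analytic expectation of per-depth and per-shell biovolume fractions.

    Computed by area-weighted averaging of the target-fraction profiles over
    the pixel grid — never from rendered images.  Rows with
    ``shell_index == -1`` are whole-section (depth-profile) expectations.
    """
    config.validate_profiles()
    slicer_params = slicer_params or SlicerParams(baseline_smoothing_fraction=0.0)
    support = config.support()
    d = config.wall_distance()
    shells = wall_distance_shells(
        BinaryMask(config.footprint(), config.pixel_size_um), slicer_params
    )
    sup_flat = support.ravel()
    d_flat = np.nan_to_num(d.ravel(), nan=0.0)
    shell_flat = shells.ravel()
    n_shells = int(shells.max()) + 1
    rows = []
    for z in config.section_depths_um:
        for probe, fn in (("aob", config.aob_profile), ("amx", config.amx_profile)):
            vals = _eval_profile(fn, z, d_flat[sup_flat])
            rows.append(
                {
                    "depth_um": float(z),
                    "shell_index": -1,
                    "probe": probe,
                    "expected_fraction": float(vals.mean()),
                }
            )
            sh = shell_flat[sup_flat]
            for s in range(n_shells):
                in_shell = sh == s
                rows.append(
                    {
                        "depth_um": float(z),
                        "shell_index": s,
                        "probe": probe,
                        "expected_fraction": float(vals[in_shell].mean())
                        if in_shell.any()
                        else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def save_stack(
    images: list[SectionImage], gt: GroundTruth, out_dir: str
) -> pd.DataFrame:
    """Write a stack as per-section TIFF + YAML sidecars, labels and truth CSV.

    Returns the manifest table (section paths and depths), also written to
    ``manifest.csv`` in ``out_dir``.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for k, img in enumerate(images):
        path = os.path.join(out_dir, f"section_{k:03d}.tif")
        write_section(img, path)
        write_labels(gt.labels[k].astype(np.int32), path.replace(".tif", "_labels.tif"))
        rows.append({"section": k, "path": path, "depth_um": img.depth_um})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    gt.depth_profile().to_csv(
        os.path.join(out_dir, "true_depth_profile.csv"), index=False
    )
    return manifest
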