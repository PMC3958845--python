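"""Section-image containers, preprocessing and TIFF IO.

A *section image* is one multi-channel cryosection micrograph of a carrier
compartment: an 8-bit intensity grid per fluorescent probe channel, a pixel
scale in µm/pixel, and the depth z (µm into the compartment) at which the
section was cut.  Preprocessing follows the standard FISH quantification
chain: fixed or gradient-weighted (RATS) intensity thresholding, single-pass
speckle noise reduction, area-mean downscaling of oversized images, and
assembly of microscope tiles into wall-to-wall compartment images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.transform import resize_local_mean

__all__ = [
    "SectionImage",
    "BinaryMask",
    "ThresholdParams",
    "FlatImageError",
    "threshold_fixed",
    "threshold_rats",
    "noise_reduce",
    "downscale_to_megapixels",
    "downscale_mask",
    "assemble_tiles",
    "write_section",
    "read_section",
    "write_labels",
    "read_labels",
]

#: Conventional channel names: reference probe mix (all bacteria), AOB probe,
#: anammox probe.
REFERENCE_CHANNEL = "EUB338mix"
AOB_CHANNEL = "Nse1472"
AMX_CHANNEL = "Bfu613"


class FlatImageError(ValueError):
    """Raised when a gradient-weighted threshold is undefined (flat image)."""


@dataclass
class SectionImage:
    """Multi-channel 2D micrograph of one cryosection.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2D ``uint8`` intensity array.  All
        channels must share the same shape.
    pixel_size_um
        Physical size of one pixel in µm (e.g. 1/3.30 µm for structure
        images acquired at 3.30 px/µm).
    depth_um
        Depth z of the section into the carrier compartment, µm.
    compartment_id
        Free-form identifier of the compartment the section came from.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    depth_um: float = 0.0
    compartment_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SectionImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if ch.dtype != np.uint8:
                raise ValueError(f"channel {name!r} is not 8-bit (dtype {ch.dtype})")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.depth_um < 0:
            raise ValueError("depth_um must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_pixels(self) -> int:
        h, w = self.shape
        return h * w

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class BinaryMask:
    """Binary (foreground/background) image with physical pixel scale."""

    data: np.ndarray
    pixel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


@dataclass
class ThresholdParams:
    """Threshold settings for one channel.

    ``fixed_cutoff`` is the 8-bit intensity cutoff used when ``method`` is
    ``"fixed"`` (the homogenized-sample procedure uses 30); ``method="rats"``
    selects gradient-weighted automatic thresholding instead.
    """

    fixed_cutoff: int = 30
    method: str = "fixed"

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_cutoff <= 255:
            raise ValueError("fixed_cutoff must lie in [0, 255]")
        if self.method not in ("fixed", "rats"):
            raise ValueError(f"unknown threshold method {self.method!r}")


def threshold_fixed(
    channel: np.ndarray, cutoff: int, pixel_size_um: float = 1.0
) -> BinaryMask:
    """Fixed-intensity threshold: foreground iff intensity >= ``cutoff``.

    The comparison is inclusive, so a cutoff of 30 keeps pixels whose
    intensity is exactly 30.
    """
    if not 0 <= cutoff <= 255:
        raise ValueError(f"cutoff {cutoff} outside [0, 255]")
    channel = np.asarray(channel)
    mask = channel >= cutoff
    return BinaryMask(mask, pixel_size_um, provenance=f"fixed>={cutoff}")


def _gradient_weights(img: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(img)
    return np.hypot(gy, gx)


def rats_threshold_value(channel: np.ndarray) -> float:
    """Gradient-weighted mean intensity (robust automatic threshold selection).

    T = sum(w * I) / sum(w) with w the local gradient magnitude; pixels near
    object edges dominate, so T lands between the background and foreground
    modes.  Raises :class:`FlatImageError` for a flat image, where the
    threshold is undefined.
    """
    img = np.asarray(channel, dtype=np.float64)
    w = _gradient_weights(img)
    wsum = w.sum()
    if wsum == 0:
        raise FlatImageError("image has zero gradient everywhere; RATS undefined")
    return float((w * img).sum() / wsum)


def threshold_rats(
    channel: np.ndarray,
    pixel_size_um: float = 1.0,
    local: bool = False,
    tile_px: int = 128,
) -> BinaryMask:
    """RATS segmentation: threshold at the gradient-weighted mean intensity.

    With ``local=True`` the threshold is computed per ``tile_px`` square tile
    (tiles with zero gradient fall back to the global threshold), a simple
    local variant for unevenly illuminated images.
    """
    img = np.asarray(channel, dtype=np.float64)
    t_global = rats_threshold_value(img)
    if not local:
        mask = img >= t_global
        return BinaryMask(mask, pixel_size_um, provenance=f"rats T={t_global:.3f}")
    mask = np.empty(img.shape, dtype=bool)
    h, w = img.shape
    for r0 in range(0, h, tile_px):
        for c0 in range(0, w, tile_px):
            tile = img[r0 : r0 + tile_px, c0 : c0 + tile_px]
            try:
                t = rats_threshold_value(tile)
            except FlatImageError:
                t = t_global
            mask[r0 : r0 + tile_px, c0 : c0 + tile_px] = tile >= t
    return BinaryMask(mask, pixel_size_um, provenance="rats-local")


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def noise_reduce(mask: BinaryMask, min_nonzero_neighbors: int = 1) -> BinaryMask:
    """Single-pass speckle removal.

    A foreground pixel is retained iff its 8-neighborhood contains at least
    ``min_nonzero_neighbors`` foreground pixels (neighbors outside the grid
    count as background); background pixels are unchanged.  One pass only —
    the neighbor counts are taken on the input mask, so removals do not
    cascade.
    """
    fg = mask.data
    counts = ndimage.convolve(
        fg.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )
    out = fg & (counts >= min_nonzero_neighbors)
    return BinaryMask(
        out, mask.pixel_size_um, provenance=mask.provenance + f"|nr>={min_nonzero_neighbors}"
    )


#: One "megapixel" in the image-analysis sense: 1024 x 1024 pixels.
MEGAPIXEL = 2**20


def downscale_to_megapixels(image: SectionImage, target_mp: float = 1.0) -> SectionImage:
    """Reduce an oversized image to at most ``target_mp`` megapixels.

    Both axes are scaled by the same factor using area-mean resampling, and
    the pixel scale is enlarged accordingly so physical dimensions are
    preserved (a 4096x4096 image becomes 1024x1024 with 4x the pixel size).
    Images already at or below the target are returned unchanged.
    """
    target_px = target_mp * MEGAPIXEL
    h, w = image.shape
    if h * w <= target_px:
        return image
    factor = math.sqrt(h * w / target_px)
    out_h, out_w = int(h // factor), int(w // factor)
    channels = {}
    for name, ch in image.channels.items():
        res = resize_local_mean(ch.astype(np.float64), (out_h, out_w))
        channels[name] = np.clip(np.rint(res), 0, 255).astype(np.uint8)
    # actual per-axis factor after flooring; axes may differ by < 1 part in 1e3
    eff = math.sqrt((h * w) / (out_h * out_w))
    return SectionImage(
        channels=channels,
        pixel_size_um=image.pixel_size_um * eff,
        depth_um=image.depth_um,
        compartment_id=image.compartment_id,
    )


def downscale_mask(mask: BinaryMask, target_mp: float = 1.0) -> BinaryMask:
    """Area-mean downscale a binary mask; re-threshold at 50% coverage."""
    target_px = target_mp * MEGAPIXEL
    h, w = mask.data.shape
    if h * w <= target_px:
        return mask
    factor = math.sqrt(h * w / target_px)
    out_h, out_w = int(h // factor), int(w // factor)
    res = resize_local_mean(mask.data.astype(np.float64), (out_h, out_w))
    eff = math.sqrt((h * w) / (out_h * out_w))
    return BinaryMask(
        res >= 0.5, mask.pixel_size_um * eff, provenance=mask.provenance + "|down"
    )


def assemble_tiles(
    tiles: list[SectionImage], offsets_px: list[tuple[int, int]]
) -> SectionImage:
    """Assemble microscope tiles into one wall-to-wall image.

    ``offsets_px`` gives each tile's (row, col) position on the common
    canvas.  Overlapping pixels are resolved by maximum intensity.  All tiles
    must share pixel size and channel set.
    """
    if len(tiles) != len(offsets_px):
        raise ValueError("one offset per tile required")
    if not tiles:
        raise ValueError("no tiles")
    px = tiles[0].pixel_size_um
    names = set(tiles[0].channels)
    for t in tiles[1:]:
        if t.pixel_size_um != px:
            raise ValueError("mismatched pixel sizes across tiles")
        if set(t.channels) != names:
            raise ValueError("mismatched channel sets across tiles")
    canvas_h = max(off[0] + t.shape[0] for t, off in zip(tiles, offsets_px))
    canvas_w = max(off[1] + t.shape[1] for t, off in zip(tiles, offsets_px))
    channels = {n: np.zeros((canvas_h, canvas_w), dtype=np.uint8) for n in names}
    for t, (r, c) in zip(tiles, offsets_px):
        h, w = t.shape
        for n in names:
            region = channels[n][r : r + h, c : c + w]
            np.maximum(region, t.channels[n], out=region)
    return SectionImage(
        channels=channels,
        pixel_size_um=px,
        depth_um=tiles[0].depth_um,
        compartment_id=tiles[0].compartment_id,
    )


# ---------------------------------------------------------------------------
# TIFF + sidecar IO


def write_section(image: SectionImage, path: str) -> None:
    """Write a section as a multi-page 8-bit TIFF plus a YAML sidecar.

    The sidecar (``<path>.yaml``) carries pixel size, depth, compartment id
    and the channel order, which plain TIFF cannot represent faithfully.
    """
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "pixel_size_um": float(image.pixel_size_um),
        "depth_um": float(image.depth_um),
        "compartment_id": image.compartment_id,
        "channels": names,
    }
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_section(path: str) -> SectionImage:
    """Read a section written by :func:`write_section`."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    with open(path + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    names = meta["channels"]
    if len(names) != stack.shape[0]:
        raise ValueError("sidecar channel count does not match TIFF pages")
    return SectionImage(
        channels={n: stack[i].astype(np.uint8) for i, n in enumerate(names)},
        pixel_size_um=float(meta["pixel_size_um"]),
        depth_um=float(meta["depth_um"]),
        compartment_id=meta.get("compartment_id", ""),
    )


def write_labels(labels: np.ndarray, path: str) -> None:
    """Write an integer label grid (e.g. shell labels) as 16-bit TIFF.

    Negative labels (background) are stored as 0 with all object labels
    shifted up by one.
    """
    arr = np.asarray(labels)
    if arr.min() < -1 or arr.max() > 2**16 - 2:
        raise ValueError("labels outside representable range")
    tifffile.imwrite(path, (arr + 1).astype(np.uint16), photometric="minisblack")


def read_labels(path: str) -> np.ndarray:
    """Read a label grid written by :func:`write_labels`."""
    return tifffile.imread(path).astype(np.int32) - 1
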