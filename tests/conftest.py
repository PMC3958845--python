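"""Shared fixtures: small synthetic configs and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fishstrat.synthetic import SyntheticConfig


def noise_free_overrides() -> dict:
    """Intensity settings that make thresholded masks equal ground truth."""
    return dict(
        foreground_intensity=(200.0, 10.0),
        background_intensity=(5.0, 2.0),
        edge_blur_sigma_px=0.0,
        speckle_rate=0.0,
        artifact_rate=0.0,
    )


@pytest.fixture
def small_config() -> SyntheticConfig:
    """Quick 9-section stack on a 500 µm compartment, noise-free render."""
    return SyntheticConfig(
        grid_size_px=200,
        pixel_size_um=2.5,
        compartment_side_um=500.0,
        section_depths_um=tuple(range(0, 801, 100)),
        seed=11,
        **noise_free_overrides(),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent of the package)


def oracle_neighbor_filter(mask: np.ndarray, min_neighbors: int = 1) -> np.ndarray:
    """Per-pixel 8-neighbor count, single pass."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        n += 1
            out[r, c] = n >= min_neighbors
    return out


def oracle_flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components by explicit flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def oracle_wall_distance(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """All-pairs pixel-center distance to the nearest background pixel.

    The one-pixel ring outside the grid counts as background; distances are
    reduced by half a pixel (center-to-wall) and floored at zero, matching
    the slicer's convention.
    """
    h, w = mask.shape
    bg = [
        (r, c)
        for r in range(-1, h + 1)
        for c in range(-1, w + 1)
        if r in (-1, h) or c in (-1, w) or not mask[r, c]
    ]
    bg = np.array(bg, dtype=float)
    out = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1)).min()
            out[r, c] = max(d - 0.5, 0.0) * pixel_size_um
    return out
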