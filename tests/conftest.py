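"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tibiamct.phantom import PhantomSpec, RadiationEffect


@pytest.fixture(scope="session")
def clean_phantom_spec() -> PhantomSpec:
    """Default-geometry phantom pair, noiseless, no effect."""
    return PhantomSpec(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """Reduced-size phantom for fast end-to-end tests."""
    return PhantomSpec(
        image_shape=(220, 88, 88),
        outer_radius_profile=(400.0, 260.0),
        cortical_thickness_profile=(100.0, 180.0),
        trabecular_region=(100.0, 900.0),
        rod_spacing=150.0,
        rod_thickness=50.0,
        noise_sd=0.0,
        seed=7,
    )


def digital_ball(diameter: float, shape: int | None = None) -> np.ndarray:
    """Digital ball of a given voxel diameter, centred in a cubic array."""
    n = shape or int(np.ceil(diameter)) + 4
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= (diameter / 2) ** 2


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive maximal-sphere thickness oracle for small (≤32³) masks.

    For every foreground voxel taken as a candidate sphere centre, the
    radius is the brute-force minimum distance to any background voxel
    (with everything outside the array counting as background), and every
    voxel strictly inside that sphere receives at least ``2 r - 1``.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    # account for background beyond the padded array: nearest outside voxel
    # is at distance (coordinate + 1) from each face, dominated by in-array
    # padding, so the single pad layer is sufficient for radii found here
    th = np.zeros(padded.shape)
    for c in fg:
        r2 = int(((bg - c) ** 2).sum(axis=1).min())  # exact integer radius²
        dd = ((fg - c) ** 2).sum(axis=1)
        covered = fg[dd < r2]  # strictly inside the inscribed ball
        val = 2.0 * np.sqrt(r2) - 1.0
        for v in covered:
            if th[tuple(v)] < val:
                th[tuple(v)] = val
    return th[1:-1, 1:-1, 1:-1]


def flood_fill_label_sizes(mask: np.ndarray) -> list:
    """Brute-force 26-connected component sizes via BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    sizes = []
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    for start in np.argwhere(mask):
        start = tuple(start)
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                        and 0 <= p[2] < mask.shape[2]
                        and mask[p] and not visited[p]):
                    visited[p] = True
                    stack.append(p)
        sizes.append(size)
    return sizes


def random_blob_mask(shape: tuple, rng: np.random.Generator,
                     threshold: float = 0.55) -> np.ndarray:
    """Smooth random blob field (thresholded filtered noise)."""
    from scipy import ndimage

    noise = rng.random(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo) > threshold
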