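"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: connected
components by breadth-first flood fill, the Feret diameter by the maximum
over *all* pixel-corner pairs, and PSD moments by plain two-pass formulas.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from nanopsd.segmentation import ParticleRegion


def brute_force_components(mask: np.ndarray, connectivity: int = 8) -> list[frozenset]:
    """Connected components by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    nrow, ncol = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(nrow):
        for c0 in range(ncol):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                comp.add((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        q.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def brute_force_feret(region: ParticleRegion, nm_per_px: float) -> float:
    """Max pairwise distance over ALL pixel corners (no convex hull)."""
    corners = set()
    for r, c in zip(region.rows.tolist(), region.cols.tolist()):
        corners.update([(c, r), (c + 1, r), (c, r + 1), (c + 1, r + 1)])
    pts = np.array(sorted(corners), dtype=np.float64)
    d2 = ((pts[:, np.newaxis, :] - pts[np.newaxis, :, :]) ** 2).sum(axis=2)
    return math.sqrt(float(d2.max())) * nm_per_px


def random_blob_region(rng: np.random.Generator, shape=(64, 64)) -> ParticleRegion:
    """A random connected pixel region inside the given grid."""
    from scipy import ndimage

    nrow, ncol = shape
    mask = np.zeros(shape, dtype=bool)
    r, c = rng.integers(4, nrow - 4), rng.integers(4, ncol - 4)
    mask[r, c] = True
    # random dilation-growth keeps the region connected
    for _ in range(int(rng.integers(2, 8))):
        grown = ndimage.binary_dilation(mask)
        keep = rng.random(mask.shape) < 0.7
        mask |= grown & keep
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:  # keep the largest piece only
        sizes = ndimage.sum_labels(mask, lab, index=range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    rows, cols = np.nonzero(mask)
    return ParticleRegion(id=1, rows=rows, cols=cols, nm_per_px=1.0)


def disk_mask(radius_px: float, pad: int = 3) -> np.ndarray:
    """Digitized disk: pixel centers within the radius."""
    n = int(math.ceil(2 * radius_px)) + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n] + 0.5
    cx = cy = n / 2
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
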