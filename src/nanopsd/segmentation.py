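"""Threshold segmentation and particle-region extraction.

The segmentation chain mirrors the standard particle-analysis workflow on
bright-field TEM micrographs: percentile thresholding of the gray histogram
(dark pixels become foreground), connected-component labelling, interior
hole filling, removal of components touching the image edge, and area
restriction in px and nm².

The threshold parameter TH is a percentage of the image's gray histogram:
for dark-foreground polarity a pixel is foreground iff its gray value is at
most the TH-th percentile of all gray values.  A low TH therefore admits only
the darkest pixels; TH = 100 admits every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Micrograph

__all__ = [
    "SegmentationConfig",
    "ParticleRegion",
    "threshold",
    "th_percent_for_gray",
    "extract_particles",
    "segment",
    "region_from_mask",
    "restriction_sweep",
]


@dataclass
class SegmentationConfig:
    """Parameters of the segmentation chain.

    Defaults follow common practice for this kind of analysis: 8-connectivity
    for "contiguous pixels", hole inclusion and edge exclusion switched on,
    and a 50 px lower size limit to suppress noise specks.
    """

    th_percent: float = 8.0
    polarity: str = "dark"  # "dark" or "light" foreground
    connectivity: int = 8  # 4 or 8
    include_holes: bool = True
    exclude_edges: bool = True
    min_area_px: int = 50
    min_area_nm2: float | None = None
    max_area_nm2: float | None = None

    def validate(self) -> None:
        if not 0 < self.th_percent <= 100:
            raise ValueError(f"th_percent must be in (0, 100], got {self.th_percent}")
        if self.polarity not in ("dark", "light"):
            raise ValueError(f"polarity must be 'dark' or 'light', got {self.polarity}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if (
            self.min_area_nm2 is not None
            and self.max_area_nm2 is not None
            and self.min_area_nm2 >= self.max_area_nm2
        ):
            raise ValueError("min_area_nm2 must be < max_area_nm2")


@dataclass
class ParticleRegion:
    """One detected connected component.

    ``rows``/``cols`` hold the pixel membership (after hole filling);
    centroids follow the package convention that pixel ``(r, c)`` has its
    center at ``(c + 0.5, r + 0.5)`` px.  ``centroid_nm`` is scene-absolute
    (it includes the micrograph's ``origin_nm``).
    """

    id: int
    rows: np.ndarray
    cols: np.ndarray
    nm_per_px: float
    touches_edge: bool = False
    holes_filled_px: int = 0
    origin_nm: tuple[float, float] = (0.0, 0.0)

    @property
    def pixel_count(self) -> int:
        return len(self.rows)

    @property
    def centroid_px(self) -> tuple[float, float]:
        return (float(self.cols.mean()) + 0.5, float(self.rows.mean()) + 0.5)

    @property
    def centroid_nm(self) -> tuple[float, float]:
        cx, cy = self.centroid_px
        return (
            self.origin_nm[0] + cx * self.nm_per_px,
            self.origin_nm[1] + cy * self.nm_per_px,
        )

    @property
    def area_nm2(self) -> float:
        return self.pixel_count * self.nm_per_px**2

    def mask(self) -> np.ndarray:
        """Tight binary mask of the region (bounding-box sized)."""
        r0, c0 = self.rows.min(), self.cols.min()
        out = np.zeros((self.rows.max() - r0 + 1, self.cols.max() - c0 + 1), dtype=bool)
        out[self.rows - r0, self.cols - c0] = True
        return out


def threshold(m: Micrograph, th_percent: float, polarity: str = "dark") -> np.ndarray:
    """Binarize by gray-histogram percentile.

    Dark polarity: foreground iff gray <= the ``th_percent``-th percentile.
    Light polarity mirrors the histogram: foreground iff gray >= the
    ``(100 - th_percent)``-th percentile.
    """
    if not 0 < th_percent <= 100:
        raise ValueError(f"th_percent must be in (0, 100], got {th_percent}")
    px = m.pixels
    if px.size == 0:
        raise ValueError("cannot threshold an empty image")
    if polarity == "dark":
        cutoff = np.percentile(px, th_percent)
        return px <= cutoff
    if polarity == "light":
        cutoff = np.percentile(px, 100.0 - th_percent)
        return px >= cutoff
    raise ValueError(f"polarity must be 'dark' or 'light', got {polarity}")


def th_percent_for_gray(m: Micrograph, gray_cutoff: float) -> float:
    """TH percentage whose percentile cutoff corresponds to a gray level.

    Returns the fraction (in %) of pixels at or below ``gray_cutoff`` —
    useful to express a physically chosen gray cutoff (e.g. halfway between
    particle and background gray) as the TH the thresholding step expects.
    """
    return float((m.pixels <= gray_cutoff).mean() * 100.0)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def extract_particles(
    mask: np.ndarray, m: Micrograph, cfg: SegmentationConfig
) -> list[ParticleRegion]:
    """Label, fill holes, drop edge-touching components, apply size limits.

    Hole filling absorbs only *background* pixels enclosed by a component;
    pixels of another component sitting inside the hole keep their own
    label.  Surviving regions are ordered row-major by centroid and get
    consecutive ids starting at 1.
    """
    cfg.validate()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != m.pixels.shape:
        raise ValueError("mask dimensions do not match the micrograph")
    structure = _structure(cfg.connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    slices = ndimage.find_objects(labels)
    regions: list[ParticleRegion] = []
    nrow, ncol = mask.shape
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        comp = labels[sl] == lab  # work on the bounding box only
        holes_filled = 0
        if cfg.include_holes:
            filled = ndimage.binary_fill_holes(comp)
            holes = filled & ~mask[sl]
            holes_filled = int(holes.sum())
            comp = comp | holes
        rows, cols = np.nonzero(comp)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        touches = bool(
            (rows == 0).any()
            or (cols == 0).any()
            or (rows == nrow - 1).any()
            or (cols == ncol - 1).any()
        )
        if cfg.exclude_edges and touches:
            continue
        count = len(rows)
        if count < cfg.min_area_px:
            continue
        area_nm2 = count * m.nm_per_px**2
        if cfg.min_area_nm2 is not None and area_nm2 < cfg.min_area_nm2:
            continue
        if cfg.max_area_nm2 is not None and area_nm2 > cfg.max_area_nm2:
            continue
        regions.append(
            ParticleRegion(
                id=0,
                rows=rows,
                cols=cols,
                nm_per_px=m.nm_per_px,
                touches_edge=touches,
                holes_filled_px=holes_filled,
                origin_nm=m.origin_nm,
            )
        )
    # row-major ordering by centroid: top to bottom, then left to right
    regions.sort(key=lambda r: (r.centroid_px[1], r.centroid_px[0]))
    for i, r in enumerate(regions, start=1):
        r.id = i
    return regions


def segment(m: Micrograph, cfg: SegmentationConfig) -> list[ParticleRegion]:
    """Threshold + extract in one call."""
    cfg.validate()
    return extract_particles(threshold(m, cfg.th_percent, cfg.polarity), m, cfg)


def region_from_mask(
    mask: np.ndarray,
    nm_per_px: float = 1.0,
    region_id: int = 1,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> ParticleRegion:
    """Build a single :class:`ParticleRegion` directly from a binary mask
    (convenience for tests and ad-hoc measurements)."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if len(rows) == 0:
        raise ValueError("mask has no foreground pixels")
    return ParticleRegion(
        id=region_id, rows=rows, cols=cols, nm_per_px=nm_per_px, origin_nm=origin_nm
    )


def restriction_sweep(
    regions: list[ParticleRegion],
    nm_per_px: float,
    intervals: list[tuple[float, float]],
) -> pd.DataFrame:
    """Count regions whose nm² area falls within each (inclusive) interval.

    This reproduces the size-restriction tuning step of the workflow, where
    the admissible area window is narrowed until spurious hits disappear.
    Returns one row per interval with the hit count and the surviving ids.
    """
    for lo, hi in intervals:
        if lo >= hi:
            raise ValueError(f"invalid interval ({lo}, {hi}): min must be < max")
    areas = {r.id: r.pixel_count * nm_per_px**2 for r in regions}
    rows = []
    for lo, hi in intervals:
        ids = sorted(i for i, a in areas.items() if lo <= a <= hi)
        rows.append(
            {
                "min_nm2": lo,
                "max_nm2": hi,
                "hit_count": len(ids),
                "surviving_ids": ids,
            }
        )
    return pd.DataFrame(rows)
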