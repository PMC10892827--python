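"""Per-particle size and shape descriptors.

For a detected region of ``n`` pixels at calibration ``s`` nm/px:

* area ``A = n * s**2``;
* equivalent circular diameter ``ECD = sqrt(4 A / pi)`` — the diameter of
  the circle with the same area, i.e. the size of the particle assuming it
  is perfectly round;
* an ellipse is fitted from the region's second central moments (each pixel
  treated as a unit square, hence the 1/12 per-pixel variance term), then
  both axes are rescaled by a common factor so the ellipse area equals the
  region area.  ``a`` and ``b`` are FULL major/minor axis lengths;
* the maximum Feret diameter ``D_f`` is the widest caliper opening of the
  region, measured over the convex hull of all pixel corners (a single
  pixel therefore has ``D_f = sqrt(2) * s``);
* reciprocal aspect ratio ``RAR = b / a`` in (0, 1] — 1 is perfectly round;
* Feret major-axis ratio ``FMR = D_f / a`` — values above 1 flag outlines
  poking beyond the fitted ellipse;
* RAR maps onto six roundness classes from "very angular" to "very
  rounded" (interval bounds 0.12 / 0.17 / 0.25 / 0.35 / 0.49 / 0.70 / 1.00,
  lower-exclusive and upper-inclusive, so a boundary value such as 0.70
  belongs to the lower class).  RAR at or below 0.12 falls outside the
  scale and is tagged ``"out of scale"`` rather than raising.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .segmentation import ParticleRegion

__all__ = [
    "EllipseFit",
    "ShapeMetrics",
    "SHAPE_CLASSES",
    "RAR_CLASS_BOUNDS",
    "OUT_OF_SCALE",
    "area_nm2",
    "ecd",
    "fit_ellipse",
    "feret_max",
    "rar",
    "fmr",
    "classify_shape",
    "measure",
    "measure_all",
    "PARTICLE_TABLE_COLUMNS",
]

SHAPE_CLASSES = (
    "very angular",
    "angular",
    "sub-angular",
    "sub-rounded",
    "rounded",
    "very rounded",
)
# (0.12, 0.17] very angular ... (0.70, 1.00] very rounded
RAR_CLASS_BOUNDS = (0.12, 0.17, 0.25, 0.35, 0.49, 0.70, 1.00)
OUT_OF_SCALE = "out of scale"

PARTICLE_TABLE_COLUMNS = [
    "id",
    "cx_nm",
    "cy_nm",
    "area_px",
    "area_nm2",
    "ecd_nm",
    "a_nm",
    "b_nm",
    "feret_nm",
    "rar",
    "fmr",
    "shape_class",
]


@dataclass(frozen=True)
class EllipseFit:
    """Moment-based ellipse with area-preserving normalisation.

    ``a``/``b`` are full axis lengths in nm (``a >= b > 0``); orientation is
    the major-axis angle against the x-axis in radians, in [0, pi).
    ``pi * (a/2) * (b/2)`` equals the region's nm² area by construction.
    """

    a: float
    b: float
    orientation: float
    centroid_nm: tuple[float, float]


@dataclass(frozen=True)
class ShapeMetrics:
    id: int
    area_nm2: float
    ecd_nm: float
    a_nm: float
    b_nm: float
    orientation: float
    feret_nm: float
    rar: float
    fmr: float
    shape_class: str
    centroid_nm: tuple[float, float]
    area_px: int


def area_nm2(region: ParticleRegion, nm_per_px: float) -> float:
    """Region area: pixel count times the pixel area."""
    if region.pixel_count < 1:
        raise ValueError("region is empty")
    return region.pixel_count * nm_per_px**2


def ecd(A: float) -> float:
    """Equivalent circular diameter of an area, ``sqrt(4 A / pi)``."""
    if A <= 0:
        raise ValueError(f"area must be positive, got {A}")
    return math.sqrt(4.0 * A / math.pi)


def fit_ellipse(region: ParticleRegion, nm_per_px: float) -> EllipseFit:
    """Second-central-moment ellipse, rescaled to the region's exact area.

    Each pixel contributes its center plus a 1/12 variance for its unit
    extent, so a ``w x h`` rectangle yields the exact continuous-rectangle
    moments (variance ``w**2 / 12``) and a single pixel a round ellipse of
    one-pixel area.  Raw full axes are ``4 * sqrt(eigenvalue)``; both are
    then multiplied by a common factor so that ``pi a b / 4`` equals the
    pixel-count area.  The axis ratio and orientation are unaffected by the
    rescaling.
    """
    n = region.pixel_count
    if n < 1:
        raise ValueError("region is empty")
    x = region.cols.astype(np.float64)
    y = region.rows.astype(np.float64)
    vxx = x.var() + 1.0 / 12.0
    vyy = y.var() + 1.0 / 12.0
    vxy = ((x - x.mean()) * (y - y.mean())).mean()
    # eigenvalues of [[vxx, vxy], [vxy, vyy]]
    tr, det = vxx + vyy, vxx * vyy - vxy**2
    disc = math.sqrt(max(tr * tr / 4.0 - det, 0.0))
    l1, l2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 0.0)
    a0, b0 = 4.0 * math.sqrt(l1), 4.0 * math.sqrt(max(l2, 1e-300))
    if abs(vxy) > 1e-12 or abs(vxx - vyy) > 1e-12:
        orientation = 0.5 * math.atan2(2.0 * vxy, vxx - vyy)
    else:
        orientation = 0.0
    orientation %= math.pi
    k = math.sqrt(n / (math.pi * a0 * b0 / 4.0))
    s = nm_per_px
    return EllipseFit(
        a=k * a0 * s,
        b=k * b0 * s,
        orientation=orientation,
        centroid_nm=region.centroid_nm,
    )


def _corner_points(region: ParticleRegion) -> np.ndarray:
    """All four outer corners of every region pixel, in px units."""
    r = region.rows[:, np.newaxis]
    c = region.cols[:, np.newaxis]
    corners = np.concatenate(
        [
            np.concatenate([c, r], axis=1),
            np.concatenate([c + 1, r], axis=1),
            np.concatenate([c, r + 1], axis=1),
            np.concatenate([c + 1, r + 1], axis=1),
        ]
    )
    return np.unique(corners, axis=0).astype(np.float64)


def feret_max(region: ParticleRegion, nm_per_px: float) -> float:
    """Maximum Feret (caliper) diameter in nm.

    Measured over pixel outer corners: the hull of the corner cloud is
    taken first, then the maximum pairwise distance over hull vertices —
    which equals the brute-force maximum over all corner pairs, since the
    diameter of a point set is attained on its convex hull.
    """
    pts = _corner_points(region)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (collinear) corner sets
            pass
    d2 = ((pts[:, np.newaxis, :] - pts[np.newaxis, :, :]) ** 2).sum(axis=2)
    return math.sqrt(float(d2.max())) * nm_per_px


def rar(fit: EllipseFit) -> float:
    """Reciprocal aspect ratio b/a, in (0, 1]."""
    if fit.b <= 0 or fit.a < fit.b:
        raise ValueError(f"need a >= b > 0, got a={fit.a}, b={fit.b}")
    return fit.b / fit.a


def fmr(d_feret: float, fit: EllipseFit) -> float:
    """Feret major-axis ratio D_f / a."""
    if fit.a <= 0:
        raise ValueError(f"major axis must be positive, got {fit.a}")
    if d_feret <= 0:
        raise ValueError(f"Feret diameter must be positive, got {d_feret}")
    return d_feret / fit.a


def classify_shape(rar_value: float) -> str:
    """Map an RAR value onto the six roundness classes.

    Intervals are lower-exclusive / upper-inclusive; RAR <= 0.12 is below
    the scale and returns ``"out of scale"``.
    """
    if not 0 < rar_value <= 1.0:
        raise ValueError(f"RAR must be in (0, 1], got {rar_value}")
    if rar_value <= RAR_CLASS_BOUNDS[0]:
        return OUT_OF_SCALE
    # first upper bound >= value, with exact hits going to the lower class
    idx = bisect_left(RAR_CLASS_BOUNDS, rar_value, lo=1) - 1
    return SHAPE_CLASSES[idx]


def measure(region: ParticleRegion, nm_per_px: float | None = None) -> ShapeMetrics:
    """Compute the full descriptor set for one region."""
    s = region.nm_per_px if nm_per_px is None else nm_per_px
    A = area_nm2(region, s)
    fit = fit_ellipse(region, s)
    d_f = feret_max(region, s)
    r = rar(fit)
    return ShapeMetrics(
        id=region.id,
        area_nm2=A,
        ecd_nm=ecd(A),
        a_nm=fit.a,
        b_nm=fit.b,
        orientation=fit.orientation,
        feret_nm=d_f,
        rar=r,
        fmr=fmr(d_f, fit),
        shape_class=classify_shape(r),
        centroid_nm=region.centroid_nm,
        area_px=region.pixel_count,
    )


def measure_all(
    regions: list[ParticleRegion], nm_per_px: float | None = None
) -> pd.DataFrame:
    """Per-particle table of all descriptors, one row per region."""
    rows = []
    for reg in regions:
        sm = measure(reg, nm_per_px)
        rows.append(
            {
                "id": sm.id,
                "cx_nm": sm.centroid_nm[0],
                "cy_nm": sm.centroid_nm[1],
                "area_px": sm.area_px,
                "area_nm2": sm.area_nm2,
                "ecd_nm": sm.ecd_nm,
                "a_nm": sm.a_nm,
                "b_nm": sm.b_nm,
                "feret_nm": sm.feret_nm,
                "rar": sm.rar,
                "fmr": sm.fmr,
                "shape_class": sm.shape_class,
            }
        )
    return pd.DataFrame(rows, columns=PARTICLE_TABLE_COLUMNS)
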