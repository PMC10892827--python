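"""Micrograph container, pixel calibration and optional preprocessing.

Coordinate conventions used throughout the package:

* pixel origin is the top-left image corner, ``x`` runs rightward along
  columns and ``y`` downward along rows;
* pixel ``(row, col)`` occupies the square ``[col, col+1) x [row, row+1)``
  in pixel units, so its center sits at ``(col + 0.5, row + 0.5)``;
* physical (nm) coordinates are ``origin_nm + px * nm_per_px``, where
  ``origin_nm`` locates the image's top-left corner in an absolute scene
  frame.  Cropping re-origins the pixel grid but advances ``origin_nm`` so
  nm-space coordinates stay scene-absolute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.filters import unsharp_mask

__all__ = [
    "Micrograph",
    "CalibrationSpec",
    "calibrate",
    "load_micrograph",
    "save_micrograph",
    "preprocess",
]

# ITU-R 601 luminance weights, the standard RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Micrograph:
    """A calibrated 8-bit grayscale micrograph.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of gray values.
    nm_per_px
        Physical size of one pixel in nanometres; must be positive.
    label
        Free-text tag, typically the magnification (e.g. ``"150k"``).
    provenance
        Source path, or ``"synthetic"`` for generated images.
    origin_nm
        ``(x, y)`` position of the image's top-left corner in the absolute
        scene frame, in nm.  Zero for images that define their own frame.
    """

    pixels: np.ndarray
    nm_per_px: float
    label: str = ""
    provenance: str = ""
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nm_per_px <= 0:
            raise ValueError(f"nm_per_px must be positive, got {self.nm_per_px}")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("gray values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_nm(self) -> float:
        return self.pixels.shape[0] * self.nm_per_px

    @property
    def width_nm(self) -> float:
        return self.pixels.shape[1] * self.nm_per_px


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel calibration: either a direct nm/px value or a scale-bar pair."""

    nm_per_px: float | None = None
    bar_length_px: float | None = None
    bar_length_nm: float | None = None


def calibrate(spec: CalibrationSpec) -> float:
    """Resolve a :class:`CalibrationSpec` to nm/px.

    The scale-bar route is the exact ratio ``bar_length_nm / bar_length_px``
    with no rounding.
    """
    if spec.nm_per_px is not None:
        if spec.nm_per_px <= 0:
            raise ValueError(f"invalid calibration: nm_per_px={spec.nm_per_px}")
        return float(spec.nm_per_px)
    if spec.bar_length_px is None or spec.bar_length_nm is None:
        raise ValueError("calibration needs nm_per_px or both bar lengths")
    if spec.bar_length_px <= 0 or spec.bar_length_nm <= 0:
        raise ValueError(
            "invalid calibration: bar lengths must be positive, got "
            f"{spec.bar_length_px} px / {spec.bar_length_nm} nm"
        )
    return float(spec.bar_length_nm) / float(spec.bar_length_px)


def _to_gray_u8(arr: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to 8-bit luminance; pass grayscale through."""
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def load_micrograph(
    path: str,
    calibration: CalibrationSpec | float,
    label: str = "",
) -> Micrograph:
    """Read a TIFF/PNG micrograph and attach its calibration."""
    if not isinstance(calibration, CalibrationSpec):
        calibration = CalibrationSpec(nm_per_px=float(calibration))
    arr = _to_gray_u8(np.asarray(iio.imread(path)))
    return Micrograph(arr, calibrate(calibration), label=label, provenance=str(path))


def save_micrograph(m: Micrograph, path: str) -> None:
    iio.imwrite(path, m.pixels)


def preprocess(
    m: Micrograph,
    crop: tuple[int, int, int, int] | None = None,
    smooth_radius: int | None = None,
    sharpen: bool = False,
) -> Micrograph:
    """Optional crop / smooth / sharpen, applied in that order.

    Parameters
    ----------
    crop
        ``(x, y, width, height)`` in pixels; must lie inside the image.
        Cropping advances ``origin_nm`` so nm coordinates remain
        scene-absolute.
    smooth_radius
        Mean-filter radius in px (kernel side ``2r + 1``).
    sharpen
        Apply an unsharp mask (radius 2 px, amount 1.0).

    With all parameters absent the returned image is gray-identical to the
    input, and the calibration is never altered by any step.
    """
    px = m.pixels
    origin = m.origin_nm
    if crop is not None:
        x, y, w, h = crop
        nrow, ncol = px.shape
        if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > ncol or y + h > nrow:
            raise ValueError(
                f"crop rectangle (x={x}, y={y}, w={w}, h={h}) outside "
                f"image bounds {ncol}x{nrow}"
            )
        px = px[y : y + h, x : x + w]
        origin = (origin[0] + x * m.nm_per_px, origin[1] + y * m.nm_per_px)
    if smooth_radius is not None and smooth_radius > 0:
        size = 2 * int(smooth_radius) + 1
        px = ndimage.uniform_filter(px.astype(np.float64), size=size, mode="reflect")
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    if sharpen:
        out = unsharp_mask(px, radius=2, amount=1.0)  # float in [0, 1]
        px = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return replace(m, pixels=px, origin_nm=origin)
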