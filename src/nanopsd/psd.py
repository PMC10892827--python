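"""Global and windowed particle-size-distribution statistics.

A PSD summary reports, for one chosen metric (area, ECD, RAR or FMR): the
particle count N, the arithmetic mean with its standard error SE (sample
standard deviation over sqrt(N)), a fixed-width histogram with the running
cumulative percentage, and the 10/25/75/90th percentiles (the box and
whisker positions of the usual PSD boxplot).

Local PSDs restrict the analysis to windows of the micrograph — by default
500 x 500 nm² areas, the window size used to probe intracellular particle
hotspots — optionally with per-window threshold and pixel-size-limit
overrides.  Particles straddling a window border are excluded, the same
rule applied at the image edge globally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging import Micrograph, preprocess
from .morphometry import OUT_OF_SCALE, SHAPE_CLASSES, measure_all
from .segmentation import SegmentationConfig, segment

__all__ = [
    "PSDSummary",
    "LocalWindow",
    "WindowReport",
    "DEFAULT_BIN_WIDTHS",
    "summarize",
    "shape_breakdown",
    "local_psd",
    "sample_windows",
]

DEFAULT_BIN_WIDTHS = {"area_nm2": 10.0, "ecd_nm": 1.0, "rar": 0.05, "fmr": 0.05}


@dataclass(frozen=True)
class PSDSummary:
    """Distribution statistics of one metric over a particle set.

    Histogram bins are half-open ``[edge, edge + width)`` on a grid aligned
    to multiples of the bin width; ``cumulative_percent`` is the running
    percentage per bin and ends at 100 for non-empty input.  ``se_flagged``
    marks the N = 1 case where the SE is reported as 0 by convention.
    """

    metric: str
    n: int
    mean: float
    se: float
    bin_edges: np.ndarray
    counts: np.ndarray
    cumulative_percent: np.ndarray
    percentiles: dict[int, float]
    se_flagged: bool = False

    @property
    def empty(self) -> bool:
        return self.n == 0


def summarize(
    metrics: pd.DataFrame | np.ndarray,
    metric: str = "ecd_nm",
    bin_width: float | None = None,
) -> PSDSummary:
    """Summarise one metric column (or a raw value array) into a PSD.

    Mean and SE agree with the plain two-pass formulas: SE is the sample
    standard deviation (n - 1 denominator) divided by sqrt(n).  Percentiles
    use linear interpolation.  Empty input yields a valid-but-empty summary.
    """
    if isinstance(metrics, pd.DataFrame):
        if metric not in metrics.columns:
            raise KeyError(f"unknown metric {metric!r}")
        values = metrics[metric].to_numpy(dtype=np.float64)
    else:
        values = np.asarray(metrics, dtype=np.float64)
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(metric, 1.0)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n = len(values)
    if n == 0:
        return PSDSummary(
            metric=metric,
            n=0,
            mean=math.nan,
            se=math.nan,
            bin_edges=np.array([]),
            counts=np.array([], dtype=int),
            cumulative_percent=np.array([]),
            percentiles={p: math.nan for p in (10, 25, 75, 90)},
        )
    mean = float(values.mean())
    if n == 1:
        se, flagged = 0.0, True
    else:
        se, flagged = float(values.std(ddof=1) / math.sqrt(n)), False
    first = math.floor(values.min() / bin_width)
    last = math.floor(values.max() / bin_width)
    idx = np.floor(values / bin_width).astype(np.int64) - first
    counts = np.bincount(idx, minlength=last - first + 1)
    edges = (np.arange(first, last + 2)) * bin_width
    cumulative = counts.cumsum() / n * 100.0
    pct = {p: float(np.percentile(values, p)) for p in (10, 25, 75, 90)}
    return PSDSummary(
        metric=metric,
        n=n,
        mean=mean,
        se=se,
        bin_edges=edges,
        counts=counts,
        cumulative_percent=cumulative,
        percentiles=pct,
        se_flagged=flagged,
    )


def shape_breakdown(classes: list[str] | pd.Series) -> dict[str, float]:
    """Percentage of particles per roundness class.

    Out-of-scale particles (RAR at or below the scale's lower bound) are
    excluded from the six-class percentages and reported separately under
    ``"out of scale"`` as a raw count.  Percentages sum to 100 for any
    non-empty in-scale input; empty input returns all zeros.
    """
    classes = list(classes)
    in_scale = [c for c in classes if c != OUT_OF_SCALE]
    out = {cls: 0.0 for cls in SHAPE_CLASSES}
    if in_scale:
        for c in in_scale:
            if c not in out:
                raise ValueError(f"unknown shape class {c!r}")
            out[c] += 1.0
        for cls in SHAPE_CLASSES:
            out[cls] = out[cls] / len(in_scale) * 100.0
    out[OUT_OF_SCALE] = float(len(classes) - len(in_scale))
    return out


@dataclass(frozen=True)
class LocalWindow:
    """A rectangular analysis window in scene (nm) coordinates, with
    optional per-window threshold / lower-pixel-limit overrides."""

    origin_nm: tuple[float, float]
    width_nm: float = 500.0
    height_nm: float = 500.0
    th_percent: float | None = None
    min_area_px: int | None = None


@dataclass(frozen=True)
class WindowReport:
    """Per-window result echoing the parameters that produced it: the
    threshold actually used, mean ± SE, particle count, lower pixel limit
    and the window origin."""

    window: LocalWindow
    th_percent: float
    min_area_px: int
    summary: PSDSummary
    particles: pd.DataFrame


def _window_rect_px(m: Micrograph, w: LocalWindow) -> tuple[int, int, int, int]:
    s = m.nm_per_px
    x0 = (w.origin_nm[0] - m.origin_nm[0]) / s
    y0 = (w.origin_nm[1] - m.origin_nm[1]) / s
    x, y = int(round(x0)), int(round(y0))
    wd, ht = int(round(w.width_nm / s)), int(round(w.height_nm / s))
    nrow, ncol = m.pixels.shape
    if x < 0 or y < 0 or wd <= 0 or ht <= 0 or x + wd > ncol or y + ht > nrow:
        raise ValueError(
            f"window at origin {w.origin_nm} nm, {w.width_nm}x{w.height_nm} nm² "
            "lies outside the micrograph"
        )
    return x, y, wd, ht


def local_psd(
    m: Micrograph,
    windows: list[LocalWindow],
    cfg: SegmentationConfig,
    metric: str = "area_nm2",
    bin_width: float | None = None,
) -> list[WindowReport]:
    """Segment and summarise each window independently.

    Each window is cropped out of the micrograph (keeping scene-absolute nm
    coordinates), segmented with the base config plus any per-window
    overrides — note the percentile threshold is evaluated on the *window's*
    gray histogram — and summarised.  Edge exclusion applies to the window
    borders, so particles cut by the window are dropped.
    """
    reports = []
    for w in windows:
        rect = _window_rect_px(m, w)
        sub = preprocess(m, crop=rect)
        wcfg = replace(
            cfg,
            th_percent=w.th_percent if w.th_percent is not None else cfg.th_percent,
            min_area_px=w.min_area_px if w.min_area_px is not None else cfg.min_area_px,
        )
        regions = segment(sub, wcfg)
        table = measure_all(regions)
        reports.append(
            WindowReport(
                window=w,
                th_percent=wcfg.th_percent,
                min_area_px=wcfg.min_area_px,
                summary=summarize(table, metric=metric, bin_width=bin_width)
                if len(table)
                else summarize(np.array([]), metric=metric, bin_width=bin_width),
                particles=table,
            )
        )
    return reports


def sample_windows(
    m: Micrograph,
    n_windows: int,
    seed: int,
    width_nm: float = 500.0,
    height_nm: float = 500.0,
) -> list[LocalWindow]:
    """Draw reproducible random window origins inside the micrograph."""
    if width_nm > m.width_nm or height_nm > m.height_nm:
        raise ValueError("window larger than the micrograph")
    rng = np.random.default_rng(seed)
    windows = []
    for _ in range(n_windows):
        x = m.origin_nm[0] + rng.uniform(0.0, m.width_nm - width_nm)
        y = m.origin_nm[1] + rng.uniform(0.0, m.height_nm - height_nm)
        windows.append(LocalWindow(origin_nm=(x, y), width_nm=width_nm, height_nm=height_nm))
    return windows
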