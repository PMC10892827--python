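"""Convenience glue: micrograph in, per-particle table out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .imaging import Micrograph, preprocess
from .morphometry import measure_all
from .segmentation import ParticleRegion, SegmentationConfig, segment

__all__ = ["ParticleAnalysis", "analyze_micrograph"]


@dataclass
class ParticleAnalysis:
    micrograph: Micrograph
    regions: list[ParticleRegion]
    particles: pd.DataFrame  # one row per particle, morphometry columns


def analyze_micrograph(
    m: Micrograph,
    cfg: SegmentationConfig,
    crop: tuple[int, int, int, int] | None = None,
    smooth_radius: int | None = None,
    sharpen: bool = False,
) -> ParticleAnalysis:
    """Preprocess, segment and measure one micrograph."""
    if crop is not None or smooth_radius is not None or sharpen:
        m = preprocess(m, crop=crop, smooth_radius=smooth_radius, sharpen=sharpen)
    regions = segment(m, cfg)
    return ParticleAnalysis(micrograph=m, regions=regions, particles=measure_all(regions))
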