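"""Ground-truth validation studies on synthetic micrographs.

These studies quantify how well the measurement chain recovers known
geometry under controlled imaging conditions, mirroring the quality-control
questions one asks of real TEM data: can the pipeline recover particle
sizes from a single well-resolved image (disk/ellipse recovery), and how
stable are the sizes across magnifications (multi-scale study)?

Thresholds are chosen physically in all studies: the gray cutoff is placed
halfway between the particle and background gray levels and converted to
the equivalent histogram-percentile TH.  The multi-scale study renders one
scene at 0.1 / 0.3 / 1.5 nm/px — the calibrations a standard 15 µm camera
pixel yields at 150,000x / 50,000x / 10,000x magnification.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .morphometry import measure_all
from .qc import MagEntry, MagnificationSeries, QCReport, deviation_table, match_particles
from .segmentation import SegmentationConfig, segment, th_percent_for_gray
from .synthgen import BackgroundSpec, match_to_truth, random_scene, render

__all__ = [
    "RecoveryResult",
    "MultiscaleResult",
    "disk_recovery_study",
    "ellipse_recovery_study",
    "multiscale_study",
    "MAG_SCALES_NM_PER_PX",
]

# 15 um physical camera pixel at 150k / 50k / 10k magnification
MAG_SCALES_NM_PER_PX = {"150k": 0.1, "50k": 0.3, "10k": 1.5}

_BASE_GRAY = 180.0


def _midpoint_cfg(m, contrast: float, **kw) -> SegmentationConfig:
    th = th_percent_for_gray(m, _BASE_GRAY + contrast / 2.0)
    return SegmentationConfig(th_percent=th, **kw)


@dataclass
class RecoveryResult:
    """Per-particle measured-vs-true table plus summary rates (in %)."""

    matched: pd.DataFrame
    n_true: int
    n_detected: int
    ecd_within_3pct_percent: float
    mean_rar: float
    very_rounded_percent: float
    joint_ok_percent: float  # ECD within 3 % AND RAR >= 0.95 AND very rounded
    axis_ratio_within_5pct_percent: float


def _recovery(scene, nm_per_px: float, seed: int, contrast: float, min_area_px: int):
    m, truth = render(scene, nm_per_px, seed=seed)
    cfg = _midpoint_cfg(m, contrast, min_area_px=min_area_px)
    table = measure_all(segment(m, cfg))
    matched = match_to_truth(table, truth, tolerance_nm=2.0 * nm_per_px * 5)
    return m, truth, matched


def disk_recovery_study(
    seed: int,
    n_disks: int = 100,
    nm_per_px: float = 0.5,
    ecd_range_nm: tuple[float, float] = (5.0, 12.0),
    contrast: float = -80.0,
    noise_sd: float = 5.0,
) -> RecoveryResult:
    """Recover known disks from one noisy rendering.

    Default conditions: 100 disks of 10-24 px diameter at 0.5 nm/px,
    80 gray levels of contrast, gray-noise SD 5.
    """
    scene = random_scene(
        n_disks,
        width_nm=1000.0,
        height_nm=1000.0,
        seed=seed,
        ecd_range_nm=ecd_range_nm,
        families=("disk",),
        contrast_range=(contrast, contrast),
        background=BackgroundSpec(base_gray=_BASE_GRAY),
        noise_sd=noise_sd,
    )
    _, truth, matched = _recovery(scene, nm_per_px, seed + 1, contrast, min_area_px=50)
    rel_err = (matched.ecd_nm - matched.true_ecd_nm).abs() / matched.true_ecd_nm
    ok_ecd = rel_err <= 0.03
    ok_rar = matched.rar >= 0.95
    ok_class = matched.shape_class == "very rounded"
    joint = ok_ecd & ok_rar & ok_class
    return RecoveryResult(
        matched=matched,
        n_true=len(truth),
        n_detected=len(matched),
        ecd_within_3pct_percent=float(ok_ecd.mean() * 100.0),
        mean_rar=float(matched.rar.mean()),
        very_rounded_percent=float(ok_class.mean() * 100.0),
        joint_ok_percent=float(joint.mean() * 100.0),
        axis_ratio_within_5pct_percent=float("nan"),
    )


def ellipse_recovery_study(
    seed: int,
    n_ellipses: int = 60,
    nm_per_px: float = 0.5,
    ecd_range_nm: tuple[float, float] = (8.0, 14.0),
    rar_range: tuple[float, float] = (0.60, 0.95),
    contrast: float = -80.0,
    noise_sd: float = 5.0,
) -> RecoveryResult:
    """Recover known ellipse axis ratios (major axis >= 15 px)."""
    scene = random_scene(
        n_ellipses,
        width_nm=1000.0,
        height_nm=1000.0,
        seed=seed,
        ecd_range_nm=ecd_range_nm,
        families=("ellipse",),
        ellipse_rar_range=rar_range,
        contrast_range=(contrast, contrast),
        background=BackgroundSpec(base_gray=_BASE_GRAY),
        noise_sd=noise_sd,
    )
    _, truth, matched = _recovery(scene, nm_per_px, seed + 1, contrast, min_area_px=50)
    true_rar = matched.true_b_nm / matched.true_a_nm
    rel = (matched.rar - true_rar).abs() / true_rar
    rel_ecd = (matched.ecd_nm - matched.true_ecd_nm).abs() / matched.true_ecd_nm
    return RecoveryResult(
        matched=matched,
        n_true=len(truth),
        n_detected=len(matched),
        ecd_within_3pct_percent=float((rel_ecd <= 0.03).mean() * 100.0),
        mean_rar=float(matched.rar.mean()),
        very_rounded_percent=float((matched.shape_class == "very rounded").mean() * 100.0),
        joint_ok_percent=float("nan"),
        axis_ratio_within_5pct_percent=float((rel <= 0.05).mean() * 100.0),
    )


@dataclass
class MultiscaleResult:
    """Cross-magnification stability of the measured ECD."""

    report: QCReport
    n_matched_at_coarsest: int
    within_1nm_percent: float  # coarsest vs reference, |dev| <= 1.0 nm
    max_abs_deviation_nm: float  # coarsest vs reference
    coarsest_label: str
    reference_label: str


def multiscale_study(
    seed: int,
    n_particles: int = 40,
    scene_nm: float = 400.0,
    scales: dict[str, float] | None = None,
    ecd_range_nm: tuple[float, float] = (3.5, 12.0),
    contrast: float = -80.0,
    noise_sd: float = 3.0,
    min_ecd_nm: float = 3.5,
) -> MultiscaleResult:
    """Render one scene at several calibrations and compare matched ECDs.

    The reference is the finest scale; particle matching uses a tolerance of
    two coarse pixels, and particles whose reference ECD falls below
    ``min_ecd_nm`` are excluded from the deviation statistics.
    """
    scales = scales or MAG_SCALES_NM_PER_PX
    labels = sorted(scales, key=scales.__getitem__)  # finest first
    scene = random_scene(
        n_particles,
        width_nm=scene_nm,
        height_nm=scene_nm,
        seed=seed,
        ecd_range_nm=ecd_range_nm,
        contrast_range=(contrast, contrast),
        background=BackgroundSpec(base_gray=_BASE_GRAY),
        noise_sd=noise_sd,
    )
    entries = []
    for label in labels:
        m, _ = render(scene, scales[label], seed=seed + 1, label=label)
        cfg = _midpoint_cfg(m, contrast, min_area_px=1, min_area_nm2=5.0)
        entries.append(
            MagEntry(
                label=label,
                particles=measure_all(segment(m, cfg)),
                th_percent=cfg.th_percent,
                nm_per_px=scales[label],
            )
        )
    series = MagnificationSeries(entries)
    matched = match_particles(series, tolerance_nm=2.0 * scales[labels[-1]])
    report = deviation_table(matched, reference=labels[0], min_ecd_nm=min_ecd_nm)
    coarse = labels[-1]
    ok = report.ecd[labels[0]] >= min_ecd_nm
    dev = report.deviations.loc[ok, coarse].dropna()
    return MultiscaleResult(
        report=report,
        n_matched_at_coarsest=int(len(dev)),
        within_1nm_percent=float((dev.abs() <= 1.0).mean() * 100.0) if len(dev) else float("nan"),
        max_abs_deviation_nm=float(dev.abs().max()) if len(dev) else float("nan"),
        coarsest_label=coarse,
        reference_label=labels[0],
    )
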