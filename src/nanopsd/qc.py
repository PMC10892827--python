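"""Quality control: cross-magnification ECD comparison and threshold
sensitivity.

The central QC question for TEM particle sizing is how stable a particle's
measured ECD is when the same specimen region is imaged at different
magnifications (different nm/px).  The procedure here matches particles
across a registered magnification series by their scene-frame centroids,
tabulates each particle's ECD per magnification, and reports signed
deviations against a chosen reference magnification — conventionally the
highest one, where the measurement is most stable.  Particles whose
reference ECD falls below 3.5 nm are excluded from the deviation statistics
by default, since sizes that small sit at the resolution limit of the
coarser images.

A second QC axis is the threshold: re-running the segmentation over a list
of TH values shows how particle count and individual ECDs respond to the
cutoff choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import Micrograph
from .morphometry import measure_all
from .segmentation import SegmentationConfig, segment

__all__ = [
    "MagEntry",
    "MagnificationSeries",
    "MatchResult",
    "QCReport",
    "entry_from_micrograph",
    "match_particles",
    "deviation_table",
    "deviation_from_measurements",
    "threshold_sensitivity",
    "ThresholdSensitivity",
]

DEFAULT_MIN_ECD_NM = 3.5


@dataclass
class MagEntry:
    """One magnification's measurements: a per-particle table with
    scene-frame centroids (``cx_nm``, ``cy_nm``) and ``ecd_nm``."""

    label: str
    particles: pd.DataFrame
    th_percent: float | None = None
    nm_per_px: float | None = None


@dataclass
class MagnificationSeries:
    """Two or more magnifications of the same scene, sharing one nm frame."""

    entries: list[MagEntry]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("a magnification series requires >= 2 entries")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate magnification labels: {labels}")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def coarsest_nm_per_px(self) -> float | None:
        vals = [e.nm_per_px for e in self.entries if e.nm_per_px is not None]
        return max(vals) if vals else None


def entry_from_micrograph(
    m: Micrograph, cfg: SegmentationConfig, label: str | None = None
) -> MagEntry:
    """Segment + measure one micrograph into a series entry."""
    table = measure_all(segment(m, cfg))
    return MagEntry(
        label=label if label is not None else m.label,
        particles=table,
        th_percent=cfg.th_percent,
        nm_per_px=m.nm_per_px,
    )


@dataclass
class MatchResult:
    """Cross-magnification particle correspondence.

    ``ecd`` is a wide table (match id x magnification label) of ECDs, where
    the match id is the particle id in the anchor (first) entry; NaN marks
    a particle not found at that magnification.  ``centroids`` holds the
    anchor centroids, ``unmatched`` the leftover particle ids per label.
    """

    ecd: pd.DataFrame
    centroids: pd.DataFrame
    unmatched: dict[str, list[int]]
    tolerance_nm: float


def match_particles(
    series: MagnificationSeries, tolerance_nm: float | None = None
) -> MatchResult:
    """Greedy one-to-one nearest-centroid matching across magnifications.

    Every non-anchor entry is matched against the first entry: candidate
    pairs within ``tolerance_nm`` are accepted in order of increasing
    distance (ties broken by lower anchor id, then lower candidate id, so
    the result is deterministic and independent of input row order).  The
    default tolerance is two pixels of the coarsest image, in nm.
    """
    if tolerance_nm is None:
        coarse = series.coarsest_nm_per_px
        if coarse is None:
            raise ValueError("no nm_per_px on any entry; pass tolerance_nm")
        tolerance_nm = 2.0 * coarse
    if tolerance_nm <= 0:
        raise ValueError("tolerance_nm must be positive")
    anchor = series.entries[0]
    ap = anchor.particles
    index = ap["id"].to_numpy()
    ecd = pd.DataFrame(index=pd.Index(index, name="particle"))
    ecd[anchor.label] = ap["ecd_nm"].to_numpy()
    centroids = pd.DataFrame(
        {"cx_nm": ap["cx_nm"].to_numpy(), "cy_nm": ap["cy_nm"].to_numpy()},
        index=ecd.index,
    )
    unmatched: dict[str, list[int]] = {anchor.label: []}
    axy = ap[["cx_nm", "cy_nm"]].to_numpy(dtype=float)
    for entry in series.entries[1:]:
        op = entry.particles
        oxy = op[["cx_nm", "cy_nm"]].to_numpy(dtype=float)
        col = pd.Series(np.nan, index=ecd.index)
        if len(ap) and len(op):
            d = np.sqrt(((axy[:, None, :] - oxy[None, :, :]) ** 2).sum(axis=2))
            ai, oj = np.nonzero(d <= tolerance_nm)
            order = sorted(
                range(len(ai)),
                key=lambda k: (d[ai[k], oj[k]], ap["id"].iat[ai[k]], op["id"].iat[oj[k]]),
            )
            used_a: set[int] = set()
            used_o: set[int] = set()
            for k in order:
                i, j = int(ai[k]), int(oj[k])
                if i in used_a or j in used_o:
                    continue
                used_a.add(i)
                used_o.add(j)
                col.loc[ap["id"].iat[i]] = op["ecd_nm"].iat[j]
            unmatched[entry.label] = sorted(
                int(op["id"].iat[j]) for j in range(len(op)) if j not in used_o
            )
        else:
            unmatched[entry.label] = [int(v) for v in op["id"]] if len(op) else []
        ecd[entry.label] = col
    # anchor particles missing from every other entry stay as rows with NaN
    return MatchResult(
        ecd=ecd, centroids=centroids, unmatched=unmatched, tolerance_nm=tolerance_nm
    )


@dataclass
class QCReport:
    """Deviation table against a reference magnification.

    ``deviations[label]`` = ECD(label) - ECD(reference), per matched
    particle; ``max_abs_deviation[label]`` is taken over particles with a
    reference ECD of at least ``min_ecd_nm`` (the reference's deviation
    against itself is identically zero).  Particles missing at the
    reference are flagged in ``missing_at_reference`` and excluded.
    """

    ecd: pd.DataFrame
    deviations: pd.DataFrame
    reference: str
    max_abs_deviation: dict[str, float]
    min_ecd_nm: float
    missing_at_reference: list[int] = field(default_factory=list)
    excluded_small: list[int] = field(default_factory=list)


def deviation_table(
    matched: MatchResult | pd.DataFrame,
    reference: str,
    min_ecd_nm: float = DEFAULT_MIN_ECD_NM,
) -> QCReport:
    """Signed ECD deviations of every magnification against the reference.

    Accepts either a :class:`MatchResult` or a pre-measured wide table
    (particle rows, one ECD column per magnification label) — the latter is
    how externally measured comparison tables are fed in.
    """
    wide = matched.ecd if isinstance(matched, MatchResult) else matched
    if reference not in wide.columns:
        raise ValueError(
            f"reference label {reference!r} not in series {list(wide.columns)}"
        )
    ref = wide[reference]
    missing = [int(i) for i in wide.index[ref.isna()]]
    dev = wide.sub(ref, axis=0)
    ok = ref.notna() & (ref >= min_ecd_nm)
    excluded_small = [int(i) for i in wide.index[ref.notna() & (ref < min_ecd_nm)]]
    max_abs = {}
    for label in wide.columns:
        vals = dev.loc[ok, label].abs().dropna()
        max_abs[label] = float(vals.max()) if len(vals) else float("nan")
    return QCReport(
        ecd=wide,
        deviations=dev,
        reference=reference,
        max_abs_deviation=max_abs,
        min_ecd_nm=min_ecd_nm,
        missing_at_reference=missing,
        excluded_small=excluded_small,
    )


def deviation_from_measurements(
    table: pd.DataFrame,
    reference: str,
    particle_col: str = "particle",
    min_ecd_nm: float = DEFAULT_MIN_ECD_NM,
) -> QCReport:
    """Deviation report from a long/wide pre-measured ECD table.

    ``table`` may already be wide (index = particle, columns = labels) or
    have a particle id column plus one ECD column per magnification.
    """
    if particle_col in table.columns:
        table = table.set_index(particle_col)
    return deviation_table(table, reference, min_ecd_nm=min_ecd_nm)


@dataclass
class ThresholdSensitivity:
    """Segmentation response to the threshold percentage."""

    summary: pd.DataFrame  # th_percent, n_particles, foreground_px
    ecd_by_threshold: pd.DataFrame  # particle (at first TH) x TH columns
    tables: list[pd.DataFrame]  # one particle table per listed TH, in order


def threshold_sensitivity(
    m: Micrograph,
    cfg: SegmentationConfig,
    th_list: list[float],
    match_tolerance_nm: float | None = None,
) -> ThresholdSensitivity:
    """Re-run segmentation + morphometry for each TH in ``th_list``.

    Reports the particle count per TH and, for particles detected at the
    first listed TH, their ECD as a function of TH (matched by centroid;
    default tolerance 2 px).
    """
    if not th_list:
        raise ValueError("th_list must be non-empty")
    for th in th_list:
        if not 0 < th <= 100:
            raise ValueError(f"th_percent must be in (0, 100], got {th}")
    from .segmentation import threshold as _threshold

    tables: list[pd.DataFrame] = []
    rows = []
    for th in th_list:
        run_cfg = replace(cfg, th_percent=th)
        mask = _threshold(m, th, cfg.polarity)
        regions = segment(m, run_cfg)
        tables.append(measure_all(regions))
        rows.append(
            {
                "th_percent": th,
                "n_particles": len(regions),
                "foreground_px": int(mask.sum()),
            }
        )
    summary = pd.DataFrame(rows)
    labels = [f"TH={th:g}[{i}]" if th_list.count(th) > 1 else f"TH={th:g}"
              for i, th in enumerate(th_list)]
    entries = [
        MagEntry(label=labels[i], particles=tables[i], nm_per_px=m.nm_per_px)
        for i in range(len(th_list))
    ]
    if len(entries) >= 2:
        tol = match_tolerance_nm or 2.0 * m.nm_per_px
        matched = match_particles(MagnificationSeries(entries), tolerance_nm=tol)
        ecd_by_th = matched.ecd
    else:
        t = tables[0]
        ecd_by_th = pd.DataFrame(
            {labels[0]: t["ecd_nm"].to_numpy()},
            index=pd.Index(t["id"], name="particle"),
        )
    return ThresholdSensitivity(
        summary=summary, ecd_by_threshold=ecd_by_th, tables=tables
    )
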