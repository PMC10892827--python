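"""Synthetic TEM-like micrographs with exact ground truth.

The generator emulates bright-field TEM micrographs of intracellular
nanoparticles: dark compact particles (gold-like disks and ellipses),
low-contrast amorphous blobs (cerium-like), and a cell-like background with
optional intensity gradient, correlated texture and a darker membrane band.
A scene is specified in physical (nm) coordinates and can be rendered at any
pixel calibration, which is how multi-magnification series of the *same*
specimen are produced: the nm-space ground truth never depends on nm/px.

Particles are rendered darker than the background (negative contrast), with
area-coverage antialiasing at the boundary so sub-pixel size recovery is
meaningful.  Geometry (including the random harmonics of amorphous blobs) is
drawn once per scene from ``SceneSpec.seed``; rendering noise is drawn from
the per-render seed after the geometry, so the geometry is noise-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Micrograph

__all__ = [
    "ParticleTruth",
    "BackgroundSpec",
    "SceneSpec",
    "Scene",
    "build_scene",
    "render",
    "random_scene",
    "match_to_truth",
    "TRUTH_COLUMNS",
]

FAMILIES = ("disk", "ellipse", "blob")

TRUTH_COLUMNS = [
    "id",
    "family",
    "cx_nm",
    "cy_nm",
    "true_area_nm2",
    "true_ecd_nm",
    "true_a_nm",
    "true_b_nm",
    "contrast",
]


@dataclass
class ParticleTruth:
    """One ground-truth particle in scene (nm) coordinates.

    ``family`` selects which geometry fields apply:

    * ``disk`` — ``radius_nm``;
    * ``ellipse`` — full axes ``a_nm >= b_nm`` and ``orientation`` (radians,
      major axis vs the x-axis);
    * ``blob`` — ``base_radius_nm`` perturbed radially by ``n_harmonics``
      random harmonics of total relative amplitude
      ``perturbation_amplitude`` (coefficients drawn at scene build time).

    ``contrast`` is the gray-level offset against the local background and
    must be negative: particles are dark in bright-field TEM.
    """

    id: int
    family: str
    centroid_nm: tuple[float, float]
    contrast: float = -80.0
    radius_nm: float | None = None
    a_nm: float | None = None
    b_nm: float | None = None
    orientation: float = 0.0
    base_radius_nm: float | None = None
    perturbation_amplitude: float = 0.20
    n_harmonics: int = 5
    # filled by build_scene for blobs: (cos coefs, sin coefs) for k = 2..
    _harmonic_coefs: tuple[np.ndarray, np.ndarray] | None = None

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"particle {self.id}: unknown family {self.family!r}")
        if self.contrast >= 0:
            raise ValueError(
                f"particle {self.id}: contrast must be negative (dark particle)"
            )
        if self.family == "disk":
            if not self.radius_nm or self.radius_nm <= 0:
                raise ValueError(f"particle {self.id}: disk needs radius_nm > 0")
        elif self.family == "ellipse":
            if not self.a_nm or not self.b_nm or self.b_nm <= 0 or self.a_nm < self.b_nm:
                raise ValueError(
                    f"particle {self.id}: ellipse needs full axes a_nm >= b_nm > 0"
                )
        else:
            if not self.base_radius_nm or self.base_radius_nm <= 0:
                raise ValueError(f"particle {self.id}: blob needs base_radius_nm > 0")
            if not 0 <= self.perturbation_amplitude < 1:
                raise ValueError(
                    f"particle {self.id}: perturbation amplitude must be in [0, 1)"
                )

    # -- analytic truth ---------------------------------------------------

    def true_area_nm2(self) -> float:
        if self.family == "disk":
            return math.pi * self.radius_nm**2
        if self.family == "ellipse":
            return math.pi * (self.a_nm / 2) * (self.b_nm / 2)
        # Blob boundary r(t) = r0 (1 + sum_k c_k cos kt + s_k sin kt);
        # the enclosed area is the exact polar integral
        # A = 1/2 \int r^2 dt = pi r0^2 (1 + (sum c_k^2 + s_k^2) / 2),
        # the limit of the shoelace polygon area as the boundary sampling
        # becomes dense.  Amplitude 0 therefore degenerates exactly to a disk.
        c, s = self._coefs()
        return math.pi * self.base_radius_nm**2 * (1.0 + 0.5 * float(c @ c + s @ s))

    def true_ecd_nm(self) -> float:
        return math.sqrt(4.0 * self.true_area_nm2() / math.pi)

    def true_axes_nm(self) -> tuple[float, float]:
        """Full major/minor axes where defined; NaN for amorphous blobs."""
        if self.family == "disk":
            return 2 * self.radius_nm, 2 * self.radius_nm
        if self.family == "ellipse":
            return self.a_nm, self.b_nm
        return math.nan, math.nan

    def max_radius_nm(self) -> float:
        if self.family == "disk":
            return self.radius_nm
        if self.family == "ellipse":
            return self.a_nm / 2
        return self.base_radius_nm * (1.0 + self.perturbation_amplitude)

    def _coefs(self) -> tuple[np.ndarray, np.ndarray]:
        if self._harmonic_coefs is None:
            z = np.zeros(self.n_harmonics)
            return z, z
        return self._harmonic_coefs

    def boundary_polygon(self, n_vertices: int = 4096) -> np.ndarray:
        """Sample the particle outline as an ``(n, 2)`` nm polygon."""
        t = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
        cx, cy = self.centroid_nm
        if self.family == "disk":
            r = np.full_like(t, self.radius_nm)
            return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
        if self.family == "ellipse":
            x = (self.a_nm / 2) * np.cos(t)
            y = (self.b_nm / 2) * np.sin(t)
            ct, st = math.cos(self.orientation), math.sin(self.orientation)
            return np.column_stack([cx + ct * x - st * y, cy + st * x + ct * y])
        r = self._blob_radius(t)
        return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])

    def _blob_radius(self, theta: np.ndarray) -> np.ndarray:
        c, s = self._coefs()
        k = np.arange(2, 2 + len(c))
        pert = np.cos(np.multiply.outer(theta, k)) @ c + np.sin(
            np.multiply.outer(theta, k)
        ) @ s
        return self.base_radius_nm * (1.0 + pert)

    def contains(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Vectorized point-in-particle test in scene coordinates."""
        cx, cy = self.centroid_nm
        dx, dy = x_nm - cx, y_nm - cy
        if self.family == "disk":
            return dx**2 + dy**2 <= self.radius_nm**2
        if self.family == "ellipse":
            ct, st = math.cos(self.orientation), math.sin(self.orientation)
            u = ct * dx + st * dy
            v = -st * dx + ct * dy
            return (u / (self.a_nm / 2)) ** 2 + (v / (self.b_nm / 2)) ** 2 <= 1.0
        r2 = dx**2 + dy**2
        theta = np.arctan2(dy, dx)
        return r2 <= self._blob_radius(theta) ** 2


@dataclass
class BackgroundSpec:
    """Cell-like background: base gray plus optional gradient, correlated
    texture and a darker membrane band (all gray levels on the 0–255 scale).
    """

    base_gray: float = 180.0
    gradient_amplitude: float = 0.0
    texture_amplitude: float = 0.0
    texture_corr_nm: float = 20.0
    membrane_x_nm: float | None = None
    membrane_width_nm: float = 0.0
    membrane_darkness: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.base_gray <= 255:
            raise ValueError("base_gray must lie in [0, 255]")
        if self.texture_amplitude < 0 or self.gradient_amplitude < 0:
            raise ValueError("background amplitudes must be non-negative")


@dataclass
class SceneSpec:
    """A physical specimen scene, independent of any pixel grid."""

    width_nm: float
    height_nm: float
    particles: list[ParticleTruth] = field(default_factory=list)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class Scene:
    """A built scene: validated spec with blob harmonics drawn and the
    analytic per-particle truth recorded."""

    spec: SceneSpec
    truth: pd.DataFrame  # nm-space ground truth, one row per particle


def build_scene(spec: SceneSpec) -> Scene:
    """Validate a :class:`SceneSpec`, draw blob harmonics, record truth.

    Blob harmonic coefficients are drawn from ``spec.seed`` (one generator,
    particles in id order) and L1-normalised to the particle's perturbation
    amplitude, so the perturbed radius stays strictly positive.
    """
    if spec.width_nm <= 0 or spec.height_nm <= 0:
        raise ValueError("scene dimensions must be positive")
    spec.background.validate()
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(spec.seed)
    outside = []
    for p in spec.particles:
        p.validate()
        if p.family == "blob" and p._harmonic_coefs is None:
            c = rng.standard_normal(p.n_harmonics)
            s = rng.standard_normal(p.n_harmonics)
            norm = np.abs(c).sum() + np.abs(s).sum()
            if norm > 0 and p.perturbation_amplitude > 0:
                scale = p.perturbation_amplitude / norm
            else:
                scale = 0.0
            p._harmonic_coefs = (c * scale, s * scale)
        cx, cy = p.centroid_nm
        if not (0 <= cx <= spec.width_nm and 0 <= cy <= spec.height_nm):
            outside.append(p.id)
    if outside:
        raise ValueError(f"particle centroids outside scene bounds: ids {outside}")
    rows = []
    for p in spec.particles:
        a_nm, b_nm = p.true_axes_nm()
        rows.append(
            {
                "id": p.id,
                "family": p.family,
                "cx_nm": p.centroid_nm[0],
                "cy_nm": p.centroid_nm[1],
                "true_area_nm2": p.true_area_nm2(),
                "true_ecd_nm": p.true_ecd_nm(),
                "true_a_nm": a_nm,
                "true_b_nm": b_nm,
                "contrast": p.contrast,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return Scene(spec=spec, truth=truth)


def _background_field(
    bg: BackgroundSpec, nrow: int, ncol: int, nm_per_px: float, rng
) -> np.ndarray:
    img = np.full((nrow, ncol), bg.base_gray, dtype=np.float64)
    if bg.gradient_amplitude > 0 and ncol > 1:
        ramp = np.linspace(-0.5, 0.5, ncol) * bg.gradient_amplitude
        img += ramp[np.newaxis, :]
    if bg.texture_amplitude > 0:
        sigma = max(bg.texture_corr_nm / nm_per_px, 1e-6)
        noise = rng.standard_normal((nrow, ncol))
        tex = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = tex.std()
        if sd > 0:
            img += tex * (bg.texture_amplitude / sd)
    if bg.membrane_x_nm is not None and bg.membrane_darkness > 0:
        x_nm = (np.arange(ncol) + 0.5) * nm_per_px
        band = np.abs(x_nm - bg.membrane_x_nm) <= bg.membrane_width_nm / 2
        img[:, band] -= bg.membrane_darkness
    return img


_SUBSAMPLES = 4  # per-axis supersampling for boundary-coverage antialiasing


def _coverage_patch(
    p: ParticleTruth, nm_per_px: float, nrow: int, ncol: int
) -> tuple[slice, slice, np.ndarray]:
    """Fractional pixel coverage of a particle over its bounding box."""
    cx, cy = p.centroid_nm
    rmax = p.max_radius_nm()
    c0 = max(int(math.floor((cx - rmax) / nm_per_px)), 0)
    c1 = min(int(math.ceil((cx + rmax) / nm_per_px)) + 1, ncol)
    r0 = max(int(math.floor((cy - rmax) / nm_per_px)), 0)
    r1 = min(int(math.ceil((cy + rmax) / nm_per_px)) + 1, nrow)
    if c1 <= c0 or r1 <= r0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    ss = _SUBSAMPLES
    off = (np.arange(ss) + 0.5) / ss
    xs = (c0 + np.add.outer(np.arange(c1 - c0), off).ravel()) * nm_per_px
    ys = (r0 + np.add.outer(np.arange(r1 - r0), off).ravel()) * nm_per_px
    inside = p.contains(xs[np.newaxis, :], ys[:, np.newaxis])
    cov = inside.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def render(
    scene: Scene, nm_per_px: float, seed: int, label: str = ""
) -> tuple[Micrograph, pd.DataFrame]:
    """Render a scene onto a pixel grid at the given calibration.

    Pixel gray = background + sum of particle ``contrast * coverage`` +
    Gaussian noise of the scene's ``noise_sd``, clipped to [0, 255] and
    quantised to 8 bit.  The returned truth table is the scene's nm-space
    truth plus pixel-space columns for this rendering and a ``sub_pixel``
    warning flag on particles covering less than one pixel.
    """
    if nm_per_px <= 0:
        raise ValueError("nm_per_px must be positive")
    spec = scene.spec
    nrow = max(int(round(spec.height_nm / nm_per_px)), 1)
    ncol = max(int(round(spec.width_nm / nm_per_px)), 1)
    if nrow < 16 or ncol < 16:
        raise ValueError(
            f"rendered image would be {ncol}x{nrow} px; at least 16x16 required"
        )
    rng = np.random.default_rng(seed)
    img = _background_field(spec.background, nrow, ncol, nm_per_px, rng)
    covers_px = []
    for p in spec.particles:
        rs, cs, cov = _coverage_patch(p, nm_per_px, nrow, ncol)
        img[rs, cs] += p.contrast * cov
        covers_px.append(float(cov.sum()))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = scene.truth.copy()
    truth["cx_px"] = truth["cx_nm"] / nm_per_px
    truth["cy_px"] = truth["cy_nm"] / nm_per_px
    truth["covers_px"] = covers_px
    truth["sub_pixel"] = truth["covers_px"] < 1.0
    m = Micrograph(
        pixels, nm_per_px, label=label or f"{nm_per_px:g} nm/px", provenance="synthetic"
    )
    return m, truth


def random_scene(
    n_particles: int,
    width_nm: float,
    height_nm: float,
    seed: int,
    ecd_range_nm: tuple[float, float] = (3.5, 12.0),
    families: tuple[str, ...] = ("disk", "ellipse", "blob"),
    contrast_range: tuple[float, float] = (-90.0, -50.0),
    ellipse_rar_range: tuple[float, float] = (0.60, 0.95),
    blob_amplitude: float = 0.15,
    margin_nm: float | None = None,
    background: BackgroundSpec | None = None,
    noise_sd: float = 5.0,
    max_tries: int = 10_000,
) -> Scene:
    """Scatter non-overlapping particles of the given nominal ECD range.

    Centres are drawn uniformly inside the margins and rejected while any
    pair is closer than the sum of maximal radii plus 1 nm, so rendered
    particles never merge.  The nominal ECD sets the analytic geometry
    (disk radius, ellipse axes, blob base radius); the recorded truth is
    always the analytic area of the generated shape.
    """
    lo, hi = ecd_range_nm
    if not 0 < lo <= hi:
        raise ValueError("invalid ECD range")
    rng = np.random.default_rng(seed)
    if margin_nm is None:
        margin_nm = hi  # keep particles clear of the image border
    particles: list[ParticleTruth] = []
    placed: list[tuple[float, float, float]] = []  # (x, y, max radius)
    tries = 0
    while len(particles) < n_particles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_particles} particles in the scene; "
                f"placed {len(particles)}"
            )
        ecd = rng.uniform(lo, hi)
        fam = families[rng.integers(len(families))]
        contrast = rng.uniform(*contrast_range)
        pid = len(particles) + 1
        if fam == "disk":
            p = ParticleTruth(pid, "disk", (0, 0), contrast, radius_nm=ecd / 2)
        elif fam == "ellipse":
            rar = rng.uniform(*ellipse_rar_range)
            p = ParticleTruth(
                pid,
                "ellipse",
                (0, 0),
                contrast,
                a_nm=ecd / math.sqrt(rar),
                b_nm=ecd * math.sqrt(rar),
                orientation=rng.uniform(0, math.pi),
            )
        else:
            p = ParticleTruth(
                pid,
                "blob",
                (0, 0),
                contrast,
                base_radius_nm=ecd / 2,
                perturbation_amplitude=blob_amplitude,
            )
        rmax = p.max_radius_nm()
        x = rng.uniform(margin_nm, width_nm - margin_nm)
        y = rng.uniform(margin_nm, height_nm - margin_nm)
        if any(
            math.hypot(x - px, y - py) < rmax + pr + 1.0 for px, py, pr in placed
        ):
            continue
        p.centroid_nm = (x, y)
        particles.append(p)
        placed.append((x, y, rmax))
    spec = SceneSpec(
        width_nm=width_nm,
        height_nm=height_nm,
        particles=particles,
        background=background or BackgroundSpec(),
        noise_sd=noise_sd,
        seed=seed,
    )
    return build_scene(spec)


def match_to_truth(
    particles: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance_nm: float | None = None,
) -> pd.DataFrame:
    """Pair measured particles with their nearest ground-truth particle.

    For each measured particle (columns ``cx_nm``/``cy_nm``) the nearest
    truth centroid is found; pairs farther apart than ``tolerance_nm`` (when
    given) are dropped.  Returns the measured table with the matched truth
    columns (prefixed ``true_``) and the centroid distance appended.
    """
    from scipy.spatial import cKDTree

    if len(particles) == 0 or len(truth) == 0:
        return particles.iloc[0:0].copy()
    tree = cKDTree(truth[["cx_nm", "cy_nm"]].to_numpy(dtype=float))
    dist, idx = tree.query(particles[["cx_nm", "cy_nm"]].to_numpy(dtype=float))
    out = particles.reset_index(drop=True).copy()
    matched = truth.iloc[idx].reset_index(drop=True)
    for col in matched.columns:
        name = col if col.startswith("true_") or col == "family" else f"true_{col}"
        if name not in out.columns:
            out[name] = matched[col].to_numpy()
    out["match_dist_nm"] = dist
    if tolerance_nm is not None:
        out = out[out["match_dist_nm"] <= tolerance_nm].reset_index(drop=True)
    return out
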