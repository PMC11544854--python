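"""Synthetic OCT / D-OCT phantoms and automated feature graders.

``generate_phantom`` renders a two-channel volume (structural OCT plus a
D-OCT-like flow channel) over a 6 mm x 6 mm field with known ground
truth for the four score items:

* a skin surface with controllable RMS roughness (and optional tilt);
* a dark epidermal band of configurable thickness, or its absence;
* a dermal pattern ~0.3 mm below the surface — periodic skin lines on
  glabrous skin, a jittered grid of dark papillary spots on hair-bearing
  skin — attenuated or removed per level 0/1/2;
* an arborizing vascular tree in the flow channel, pruned per level:
  level 1 removes the thinnest-width quantile of segments (small vessels
  disappear first), level 2 keeps only unbranched trunks.

The graders close the loop from image back to score: surface extraction
by first-crossing detection, RMS roughness after plane detrend, epidermal
band contrast, pattern regularity at the 0.3 mm en-face slice (spectral
peak prominence for skin lines, spot density for papillary spots), and
skeleton branch-point density of the flow projection. All depth data are
measured from the detected surface, so a tilted phantom grades like an
untilted one. Grader thresholds are calibrated on phantoms, not on
patients, and carry no clinical validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import skeletonize

from .errors import PhantomSpecError, SurfaceNotFoundError
from .score import FeatureGrades, SkinType

__all__ = [
    "PhantomSpec",
    "OCTVolume",
    "SurfaceMap",
    "GraderConfig",
    "AutoGradeReport",
    "generate_phantom",
    "extract_surface",
    "grade_surface",
    "grade_epidermis",
    "grade_dermal_pattern",
    "grade_vasculature",
    "grade_volume",
    "default_phantom_grid",
]

# nominal layer intensities of the structural channel
_AIR = 0.03
_EPIDERMIS = 0.18
_DERMIS = 0.65
_PATTERN_DEPTH_UM = 300.0  # depth of the dermal pattern below the surface
_PATTERN_HALF_UM = 40.0  # half-thickness of the pattern layer
_VESSEL_BAND_UM = (150.0, 450.0)  # flow-channel depth band below surface
_VESSEL_INTENSITY = 0.8


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom volume.

    ``dermal_pattern_level`` / ``vascular_level`` follow the score-item
    convention: 0 intact, 1 partially degraded, 2 lost.
    """

    skin_type: SkinType
    surface_roughness_um: float = 5.0
    epidermis_present: bool = True
    epidermis_thickness_um: float = 120.0
    dermal_pattern_level: int = 0
    vascular_level: int = 0
    noise_sd: float = 0.02
    seed: int = 0
    tilt_um_per_mm: float = 0.0
    field_of_view_mm: tuple[float, float] = (6.0, 6.0)
    depth_mm: float = 1.2
    voxel_um: tuple[float, float, float] = (8.0, 24.0, 24.0)  # dz, dy, dx

    def validate(self) -> "PhantomSpec":
        if not isinstance(self.skin_type, SkinType):
            raise PhantomSpecError("skin_type must be a SkinType")
        if self.dermal_pattern_level not in (0, 1, 2):
            raise PhantomSpecError("dermal_pattern_level must be 0, 1 or 2")
        if self.vascular_level not in (0, 1, 2):
            raise PhantomSpecError("vascular_level must be 0, 1 or 2")
        if self.surface_roughness_um < 0:
            raise PhantomSpecError("surface_roughness_um must be >= 0")
        if self.epidermis_present and self.epidermis_thickness_um <= 0:
            raise PhantomSpecError(
                "epidermis_thickness_um must be > 0 when epidermis_present"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if min(self.field_of_view_mm) <= 0 or self.depth_mm <= 0:
            raise PhantomSpecError("field of view and depth must be > 0")
        if min(self.voxel_um) <= 0:
            raise PhantomSpecError("voxel sizes must be > 0")
        return self


@dataclass
class OCTVolume:
    """Two-channel volume: structural OCT and D-OCT-like flow signal.

    Arrays are indexed (z, y, x) with z increasing into the skin; values
    lie in [0, 1]. ``meta`` carries generator ground truth when the
    volume is synthetic.
    """

    structural: np.ndarray
    vascular: np.ndarray
    voxel_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structural.shape != self.vascular.shape:
            raise PhantomSpecError("channels must share one shape")
        if self.structural.ndim != 3:
            raise PhantomSpecError("volume must be 3-D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.structural.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SurfaceMap:
    """Detected surface height per lateral position, in um from the top."""

    height_um: np.ndarray  # (ny, nx)
    coverage: float  # fraction of columns with a direct crossing


@dataclass(frozen=True)
class GraderConfig:
    """Decision thresholds of the automated graders.

    Calibrated on the phantom generator's default contrast/noise; the
    two-threshold pairs split each 0-2 item: statistic >= first -> 0,
    >= second -> 1, else 2 (pattern statistics decrease as damage grows;
    so does branch density).
    """

    rough_rms_um: float = 20.0  # surface grade 1 above this RMS
    band_contrast_min: float = 0.20  # epidermal loss below this contrast
    epidermis_band_um: tuple[float, float] = (16.0, 96.0)
    dermis_ref_um: tuple[float, float] = (160.0, 250.0)
    line_peak_ratio: tuple[float, float] = (1.3e5, 1.2e3)  # glabrous spectral
    spot_density_per_mm2: tuple[float, float] = (7.0, 1.5)  # hair-bearing
    branch_density_per_mm2: tuple[float, float] = (4.0, 0.4)
    vessel_mask_threshold: float = 0.4
    small_vessel_width_um: float = 30.0
    spot_min_separation_um: float = 150.0
    spot_min_depth: float = 0.10  # minimum darkness of a detected spot


@dataclass(frozen=True)
class AutoGradeReport:
    """Automated grades plus the measurements they were derived from."""

    grades: FeatureGrades
    measurements: dict[str, float]


def _voxel_grid(spec: PhantomSpec) -> tuple[int, int, int]:
    dz, dy, dx = spec.voxel_um
    nz = int(round(spec.depth_mm * 1000.0 / dz))
    ny = int(round(spec.field_of_view_mm[0] * 1000.0 / dy))
    nx = int(round(spec.field_of_view_mm[1] * 1000.0 / dx))
    return nz, ny, nx


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_px: float) -> np.ndarray:
    """Unit-RMS correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px,
                                mode="wrap")
    rms = float(np.sqrt(np.mean(f**2)))
    return f / rms if rms > 0 else f


def _surface_height(spec: PhantomSpec, rng: np.random.Generator,
                    ny: int, nx: int) -> np.ndarray:
    dz, dy, dx = spec.voxel_um
    x_mm = (np.arange(nx) * dx / 1000.0)[None, :]
    base = 100.0 + spec.tilt_um_per_mm * x_mm  # um from the volume top
    rough = np.zeros((ny, nx))
    if spec.surface_roughness_um > 0:
        corr_px = 150.0 / dy  # ~150 um lateral correlation length
        rough = _smooth_field(rng, (ny, nx), corr_px) * spec.surface_roughness_um
    height = base + rough
    # keep at least 3 voxels of air above the highest surface point
    floor = 3.0 * dz
    if height.min() < floor:
        height = height - height.min() + floor
    return height


def _glabrous_pattern(spec: PhantomSpec, rng: np.random.Generator,
                      ny: int, nx: int) -> tuple[np.ndarray, dict]:
    """Skin-line pattern in [0, 1]; 1 = maximally dark."""
    dz, dy, dx = spec.voxel_um
    y_um = (np.arange(ny) * dy)[:, None]
    x_um = (np.arange(nx) * dx)[None, :]
    theta = rng.uniform(0.0, np.pi)
    period_um = 400.0
    u = x_um * np.cos(theta) + y_um * np.sin(theta)
    phase = _smooth_field(rng, (ny, nx), 500.0 / dy) * 0.6  # gentle wiggle
    pattern = 0.5 * (1.0 + np.cos(2.0 * np.pi * u / period_um + phase))
    level = spec.dermal_pattern_level
    if level == 0:
        amp = 0.5
    elif level == 1:
        amp = 0.35
        pattern = ndimage.gaussian_filter(pattern, 80.0 / dy)
    else:
        amp = 0.0
    return amp * pattern, {"line_period_um": period_um, "line_theta": theta}


def _hair_pattern(spec: PhantomSpec, rng: np.random.Generator,
                  ny: int, nx: int) -> tuple[np.ndarray, dict]:
    """Papillary-spot pattern in [0, 1]; 1 = maximally dark."""
    dz, dy, dx = spec.voxel_um
    spacing_um, jitter_um, sigma_um = 300.0, 30.0, 45.0
    fy = spec.field_of_view_mm[0] * 1000.0
    fx = spec.field_of_view_mm[1] * 1000.0
    gy = np.arange(spacing_um / 2, fy, spacing_um)
    gx = np.arange(spacing_um / 2, fx, spacing_um)
    cy, cx = np.meshgrid(gy, gx, indexing="ij")
    centers = np.stack([cy.ravel(), cx.ravel()], axis=1)
    centers = centers + rng.normal(0.0, jitter_um, centers.shape)
    level = spec.dermal_pattern_level
    if level == 0:
        amp, keep = 0.55, np.ones(len(centers), dtype=bool)
    elif level == 1:
        amp = 0.35
        keep = rng.random(len(centers)) < 0.45
    else:
        amp, keep = 0.0, np.zeros(len(centers), dtype=bool)
    centers = centers[keep]
    pattern = np.zeros((ny, nx))
    if len(centers):
        # stamp Gaussian bumps on a fine grid via a delta image + blur
        deltas = np.zeros((ny, nx))
        iy = np.clip(np.round(centers[:, 0] / dy).astype(int), 0, ny - 1)
        ix = np.clip(np.round(centers[:, 1] / dx).astype(int), 0, nx - 1)
        np.add.at(deltas, (iy, ix), 1.0)
        pattern = ndimage.gaussian_filter(deltas, sigma_um / dy)
        peak = 1.0 / (2.0 * np.pi * (sigma_um / dy) * (sigma_um / dx))
        pattern = np.clip(pattern / peak, 0.0, 1.0)
    return amp * pattern, {
        "spot_count": int(len(centers)),
        "spot_spacing_um": spacing_um,
    }


@dataclass
class _Segment:
    y0: float
    x0: float
    y1: float
    x1: float
    width_um: float
    generation: int
    parent: int  # index into segment list, -1 for trunk


def _grow_tree(spec: PhantomSpec, rng: np.random.Generator) -> list[_Segment]:
    """Recursive arborizing tree over the field, en-face, in um coords."""
    fy = spec.field_of_view_mm[0] * 1000.0
    fx = spec.field_of_view_mm[1] * 1000.0
    n_trunks = 4
    max_gen = 4
    segments: list[_Segment] = []
    trunk_y = (np.arange(n_trunks) + 0.5) * fy / n_trunks
    for t in range(n_trunks):
        # trunks run left->right with a small random heading
        start = np.array([trunk_y[t] + rng.normal(0, fy * 0.02), 0.0])
        heading = rng.normal(0.0, 0.12)
        frontier = [(start, heading, 0, -1)]
        while frontier:
            pos, ang, gen, parent = frontier.pop()
            length = 1400.0 * 0.72**gen
            width = 55.0 * 0.68**gen
            # gentle curvature: split into 3 steps with heading jitter
            p = pos.copy()
            a = ang
            idx0 = len(segments)
            for _ in range(3):
                a += rng.normal(0.0, 0.10)
                q = p + (length / 3.0) * np.array([np.sin(a), np.cos(a)])
                segments.append(
                    _Segment(p[0], p[1], q[0], q[1], width, gen, parent)
                )
                parent = len(segments) - 1
                p = q
            if gen < max_gen and 0 <= p[0] <= fy and 0 <= p[1] <= fx:
                spread = rng.uniform(0.35, 0.7)
                for sign in (+1, -1):
                    child_ang = a + sign * spread + rng.normal(0.0, 0.08)
                    frontier.append((p.copy(), child_ang, gen + 1, parent))
            del idx0
    return segments


def _prune_tree(segments: list[_Segment], level: int) -> list[int]:
    """Indices of segments kept at the given vascular damage level."""
    if level == 0:
        return list(range(len(segments)))
    if level == 1:
        widths = np.array([s.width_um for s in segments])
        cutoff = float(np.quantile(widths, 0.6))
        return [i for i, s in enumerate(segments) if s.width_um > cutoff]
    return [i for i, s in enumerate(segments) if s.generation == 0]


def _junction_count(segments: list[_Segment], kept: list[int]) -> int:
    """Branchings among kept segments: parents with a kept deeper child."""
    kept_set = set(kept)
    parents = {
        segments[j].parent
        for j in kept
        if segments[j].parent >= 0
        and segments[j].generation
        == segments[segments[j].parent].generation + 1
    }
    return len(parents & kept_set)


def _render_tree(segments: list[_Segment], spec: PhantomSpec,
                 ny: int, nx: int) -> np.ndarray:
    """Binary en-face vessel mask from stamped disks along each segment."""
    dz, dy, dx = spec.voxel_um
    by_radius: dict[int, list[tuple[int, int]]] = {}
    for s in segments:
        r_px = max(1, int(round(s.width_um / 2.0 / dx)))
        length = float(np.hypot(s.y1 - s.y0, s.x1 - s.x0))
        n_steps = max(2, int(length / (dx * 0.75)))
        ts = np.linspace(0.0, 1.0, n_steps)
        ys = np.round((s.y0 + ts * (s.y1 - s.y0)) / dy).astype(int)
        xs = np.round((s.x0 + ts * (s.x1 - s.x0)) / dx).astype(int)
        ok = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
        by_radius.setdefault(r_px, []).extend(zip(ys[ok], xs[ok]))
    mask = np.zeros((ny, nx), dtype=bool)
    for r_px, pts in by_radius.items():
        if not pts:
            continue
        canvas = np.zeros((ny, nx), dtype=bool)
        iy, ix = zip(*pts)
        canvas[list(iy), list(ix)] = True
        if r_px > 1:
            yy, xx = np.ogrid[-r_px:r_px + 1, -r_px:r_px + 1]
            canvas = ndimage.binary_dilation(
                canvas, structure=yy**2 + xx**2 <= r_px**2
            )
        mask |= canvas
    return mask


def generate_phantom(spec: PhantomSpec) -> OCTVolume:
    """Render a phantom volume; bit-identical for identical spec + seed."""
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = _voxel_grid(spec)
    dz, dy, dx = spec.voxel_um

    surface_um = _surface_height(spec, rng, ny, nx)
    z_um = ((np.arange(nz) + 0.5) * dz)[:, None, None].astype(np.float32)
    depth = z_um - surface_um[None].astype(np.float32)  # um below surface

    if spec.skin_type is SkinType.GLABROUS:
        pattern, pattern_meta = _glabrous_pattern(spec, rng, ny, nx)
    else:
        pattern, pattern_meta = _hair_pattern(spec, rng, ny, nx)

    epi_t = spec.epidermis_thickness_um if spec.epidermis_present else 0.0
    structural = np.full((nz, ny, nx), _AIR, dtype=np.float32)
    tissue = depth >= 0
    if epi_t > 0:
        epi = tissue & (depth < epi_t)
        structural[epi] = _EPIDERMIS
    dermis = depth >= epi_t
    atten = np.exp(-np.clip(depth - epi_t, 0.0, None) / 2000.0,
                   dtype=np.float32)
    structural[dermis] = (_DERMIS * atten)[dermis]
    # dermal pattern layer as a multiplicative darkening around 0.3 mm
    layer = (np.abs(depth - _PATTERN_DEPTH_UM) <= _PATTERN_HALF_UM)
    structural *= 1.0 - layer * pattern[None].astype(np.float32)

    tree = _grow_tree(spec, rng)
    kept_idx = _prune_tree(tree, spec.vascular_level)
    kept = [tree[i] for i in kept_idx]
    vessel_mask = _render_tree(kept, spec, ny, nx)
    vascular = np.full((nz, ny, nx), 0.02, dtype=np.float32)
    band = (depth >= _VESSEL_BAND_UM[0]) & (depth <= _VESSEL_BAND_UM[1])
    vascular += band * (vessel_mask[None] * (_VESSEL_INTENSITY - 0.02))

    if spec.noise_sd > 0:
        # truncated additive Gaussian on both channels
        noise = rng.normal(0.0, spec.noise_sd, (2, nz, ny, nx))
        np.clip(noise, -3 * spec.noise_sd, 3 * spec.noise_sd, out=noise)
        structural += noise[0].astype(np.float32)
        vascular += noise[1].astype(np.float32)
    np.clip(structural, 0.0, 1.0, out=structural)
    np.clip(vascular, 0.0, 1.0, out=vascular)

    junctions = _junction_count(tree, kept_idx)
    meta = {
        "spec": spec,
        "surface_um": surface_um,
        "junction_count": junctions,
        "n_segments": len(kept),
        **pattern_meta,
    }
    return OCTVolume(structural=structural, vascular=vascular,
                     voxel_um=spec.voxel_um, meta=meta)


# --------------------------------------------------------------------------
# graders
# --------------------------------------------------------------------------

def extract_surface(volume: OCTVolume) -> SurfaceMap:
    """First-crossing surface detection on the structural channel.

    Per lateral position, the shallowest depth where intensity exceeds an
    adaptive air/tissue threshold on two consecutive voxels. Columns
    without a crossing are filled from their nearest detected neighbour;
    the direct-detection coverage is reported.
    """
    s = volume.structural
    if s.size == 0:
        raise SurfaceNotFoundError("surface not found: empty volume")
    dz = volume.voxel_um[0]
    air_est = float(np.median(s[0]))
    tissue_est = float(np.median(s[s.shape[0] // 2:]))
    if tissue_est - air_est < 0.05:
        raise SurfaceNotFoundError(
            "surface not found: no air/tissue contrast "
            f"(air~{air_est:.3f}, tissue~{tissue_est:.3f})"
        )
    thr = air_est + 0.25 * (tissue_est - air_est)
    above = s > thr
    hit = above[:-1] & above[1:]  # two consecutive voxels above threshold
    found = hit.any(axis=0)
    coverage = float(found.mean())
    if coverage < 0.5:
        raise SurfaceNotFoundError(
            f"surface not found: crossing in only {coverage:.0%} of columns"
        )
    idx = hit.argmax(axis=0).astype(float)
    if not found.all():
        # nearest-neighbour completion for missed columns
        _, (fy, fx) = ndimage.distance_transform_edt(
            ~found, return_indices=True
        )
        idx = np.where(found, idx, idx[fy, fx])
    height = ndimage.median_filter(idx, size=3) * dz
    return SurfaceMap(height_um=height, coverage=coverage)


def _detrended_rms(height_um: np.ndarray) -> float:
    ny, nx = height_um.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    a = np.stack([yy.ravel(), xx.ravel(), np.ones(yy.size)], axis=1)
    coef, *_ = np.linalg.lstsq(a, height_um.ravel(), rcond=None)
    resid = height_um.ravel() - a @ coef
    return float(np.sqrt(np.mean(resid**2)))


def grade_surface(
    height_map: SurfaceMap, config: GraderConfig = GraderConfig()
) -> tuple[int, dict[str, float]]:
    """Surface-irregularity grade from plane-detrended RMS roughness."""
    rms = _detrended_rms(height_map.height_um)
    grade = 1 if rms > config.rough_rms_um else 0
    return grade, {"surface_rms_um": rms}


def _enface_band_mean(volume: OCTVolume, surface: SurfaceMap,
                      depth_range_um: tuple[float, float]) -> np.ndarray:
    """Mean structural intensity over a surface-relative depth band."""
    dz = volume.voxel_um[0]
    nz = volume.shape[0]
    lo = np.round((surface.height_um + depth_range_um[0]) / dz).astype(int)
    hi = np.round((surface.height_um + depth_range_um[1]) / dz).astype(int)
    lo = np.clip(lo, 0, nz - 1)
    hi = np.clip(hi, 0, nz - 1)
    n = int(np.median(hi - lo)) + 1
    offs = np.arange(max(n, 1))
    idx = np.clip(lo[None] + offs[:, None, None], 0, nz - 1)
    return np.take_along_axis(volume.structural, idx, axis=0).mean(axis=0)


def grade_epidermis(
    volume: OCTVolume, surface: SurfaceMap,
    config: GraderConfig = GraderConfig(),
) -> tuple[int, dict[str, float]]:
    """Epidermal-loss grade from dark-band contrast against the dermis.

    Contrast = mean dermis reference intensity minus mean intensity in
    the expected band region just below the surface; an intact dark band
    gives a large positive contrast, a missing band ~0.
    """
    band = _enface_band_mean(volume, surface, config.epidermis_band_um)
    dermis = _enface_band_mean(volume, surface, config.dermis_ref_um)
    contrast = float(dermis.mean() - band.mean())
    grade = 1 if contrast < config.band_contrast_min else 0
    return grade, {"band_contrast": contrast}


def _enface_slice(volume: OCTVolume, surface: SurfaceMap,
                  depth_um: float, half_um: float) -> np.ndarray:
    return _enface_band_mean(
        volume, surface, (depth_um - half_um, depth_um + half_um)
    )


def _line_peak_ratio(slice2d: np.ndarray, voxel_yx_um: tuple[float, float]
                     ) -> float:
    """Prominence of the dominant periodic component in the slice.

    Ratio of the strongest 2-D spectral peak in the 180-800 um band to
    the median band power; a crisp line pattern gives a large ratio.
    """
    dy, dx = voxel_yx_um
    ny, nx = slice2d.shape
    win = np.hanning(ny)[:, None] * np.hanning(nx)[None, :]
    f = np.fft.fftshift(np.abs(np.fft.fft2((slice2d - slice2d.mean()) * win)) ** 2)
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=dy))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=dx))[None, :]
    fr = np.sqrt(fy**2 + fx**2)
    band = (fr >= 1.0 / 800.0) & (fr <= 1.0 / 180.0)
    if not band.any():
        return 0.0
    p = f[band]
    med = float(np.median(p))
    return float(p.max() / (med + 1e-12))


def _spot_stats(slice2d: np.ndarray, voxel_yx_um: tuple[float, float],
                config: GraderConfig) -> tuple[float, float, int]:
    """Papillary-spot density (per mm^2) and NN-spacing CV."""
    dy, dx = voxel_yx_um
    smooth = ndimage.gaussian_filter(slice2d, 30.0 / dy)
    darkness = ndimage.gaussian_filter(slice2d, 300.0 / dy) - smooth
    min_dist = max(1, int(config.spot_min_separation_um / dy))
    peaks = peak_local_max(
        darkness, min_distance=min_dist,
        threshold_abs=config.spot_min_depth, exclude_border=False,
    )
    area_mm2 = slice2d.shape[0] * dy * slice2d.shape[1] * dx / 1e6
    density = len(peaks) / area_mm2
    cv = float("nan")
    if len(peaks) >= 3:
        from scipy.spatial import cKDTree

        pts = peaks * np.array([dy, dx])
        dists, _ = cKDTree(pts).query(pts, k=2)
        nn = dists[:, 1]
        cv = float(nn.std() / nn.mean()) if nn.mean() > 0 else float("nan")
    return density, cv, len(peaks)


def _two_threshold_grade(stat: float, thresholds: tuple[float, float]) -> int:
    hi, lo = thresholds
    if stat >= hi:
        return 0
    if stat >= lo:
        return 1
    return 2


def grade_dermal_pattern(
    volume: OCTVolume, surface: SurfaceMap, skin_type: SkinType,
    config: GraderConfig = GraderConfig(),
) -> tuple[int, dict[str, float]]:
    """Dermal-pattern grade from the en-face slice 0.3 mm below the surface.

    Glabrous: spectral peak prominence of the skin-line pattern.
    Hair-bearing: papillary spot density (nearest-neighbour spacing CV is
    reported as a regularity measurement).
    """
    slice2d = _enface_slice(volume, surface, _PATTERN_DEPTH_UM,
                            _PATTERN_HALF_UM)
    voxel_yx = (volume.voxel_um[1], volume.voxel_um[2])
    if skin_type is SkinType.GLABROUS:
        stat = _line_peak_ratio(slice2d, voxel_yx)
        grade = _two_threshold_grade(stat, config.line_peak_ratio)
        return grade, {"pattern_regularity": stat}
    density, cv, count = _spot_stats(slice2d, voxel_yx, config)
    grade = _two_threshold_grade(density, config.spot_density_per_mm2)
    return grade, {
        "pattern_regularity": density,
        "spot_count": float(count),
        "spot_spacing_cv": cv,
    }


def _branch_points(skeleton: np.ndarray) -> np.ndarray:
    """Skeleton pixels with 3 or more 8-connected skeleton neighbours."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbours = ndimage.convolve(skeleton.astype(int), kernel,
                                  mode="constant")
    return skeleton & (neighbours >= 3)


def grade_vasculature(
    volume: OCTVolume, config: GraderConfig = GraderConfig()
) -> tuple[int, dict[str, float]]:
    """Vascular grade from branch-point density of the flow projection.

    The en-face maximum-intensity projection of the flow channel is
    binarised and skeletonised; arborization is quantified as skeleton
    branch points per mm^2. Mean vessel width and the fraction of
    skeleton length below the small-vessel width are reported.
    """
    dy, dx = volume.voxel_um[1], volume.voxel_um[2]
    mip = volume.vascular.max(axis=0)
    mask = mip > config.vessel_mask_threshold
    measurements = {
        "branch_density_per_mm2": 0.0,
        "mean_vessel_width_um": 0.0,
        "small_vessel_fraction": 0.0,
    }
    if mask.any():
        mask = ndimage.binary_closing(mask, np.ones((3, 3), dtype=bool))
        skel = skeletonize(mask)
        area_mm2 = mask.shape[0] * dy * mask.shape[1] * dx / 1e6
        branches = _branch_points(skel)
        measurements["branch_density_per_mm2"] = float(
            branches.sum() / area_mm2
        )
        if skel.any():
            widths = ndimage.distance_transform_edt(
                mask, sampling=(dy, dx)
            )[skel] * 2.0
            measurements["mean_vessel_width_um"] = float(widths.mean())
            measurements["small_vessel_fraction"] = float(
                (widths < config.small_vessel_width_um).mean()
            )
    grade = _two_threshold_grade(
        measurements["branch_density_per_mm2"], config.branch_density_per_mm2
    )
    return grade, measurements


def grade_volume(
    volume: OCTVolume, skin_type: SkinType,
    config: GraderConfig = GraderConfig(),
) -> AutoGradeReport:
    """Run the four graders and assemble validated feature grades."""
    surface = extract_surface(volume)
    g_surf, m_surf = grade_surface(surface, config)
    g_epi, m_epi = grade_epidermis(volume, surface, config)
    g_derm, m_derm = grade_dermal_pattern(volume, surface, skin_type, config)
    g_vasc, m_vasc = grade_vasculature(volume, config)
    grades = FeatureGrades(
        surface_irregularity=g_surf,
        epidermal_loss=g_epi,
        dermal_pattern=g_derm,
        vascular_network=g_vasc,
        skin_type=skin_type,
    )
    measurements = {
        **m_surf, **m_epi, **m_derm, **m_vasc,
        "surface_coverage": surface.coverage,
    }
    return AutoGradeReport(grades=grades, measurements=measurements)


def default_phantom_grid(
    n_seeds: int = 10,
    skin_type: SkinType = SkinType.HAIR_BEARING,
    base_seed: int = 0,
) -> list[PhantomSpec]:
    """The 3x3 (dermal x vascular level) x n_seeds evaluation grid.

    Surface and epidermis are held at their healthy defaults so every
    item has a known ground-truth grade on each cell. Cells share the
    seed set (seed = base_seed + k), so level-to-level comparisons at a
    fixed k differ only in the degradation level.
    """
    grid = []
    for dermal in (0, 1, 2):
        for vasc in (0, 1, 2):
            for k in range(n_seeds):
                grid.append(
                    PhantomSpec(
                        skin_type=skin_type,
                        dermal_pattern_level=dermal,
                        vascular_level=vasc,
                        seed=base_seed + k,
                    )
                )
    return grid


def ground_truth_grades(spec: PhantomSpec) -> FeatureGrades:
    """The grades a perfect grader would assign to a phantom's spec.

    Surface grade 1 above the grader's roughness threshold; epidermal
    loss 1 when the band is absent; dermal and vascular grades equal the
    generator levels.
    """
    cfg = GraderConfig()
    return FeatureGrades(
        surface_irregularity=1 if spec.surface_roughness_um > cfg.rough_rms_um
        else 0,
        epidermal_loss=0 if spec.epidermis_present else 1,
        dermal_pattern=spec.dermal_pattern_level,
        vascular_network=spec.vascular_level,
        skin_type=spec.skin_type,
    )
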