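"""Ground-truthed synthetic STED images of ER sheets, nanoholes, and tubules.

The generator reproduces the imaging physics end to end:

1. **Geometry** — a 50-nm-thick luminal slab perforated by torus-edged
   holes.  Each hole removes a central cylinder (out to the torus equator,
   the stated *inner diameter*) plus the inner half of a torus with tube
   radius ``t/2``, so the lumen's edge follows the curved membrane rim.
   Hole centers sit on a square grid spaced 105 display pixels curved
   edge to curved edge and are jittered uniformly by ±0.5 pixel per axis
   so holes are never pixel-aligned.
2. **Projection** — the model is built with 1-nm axial voxels on a
   laterally supersampled grid (2.1-nm subpixels, 9× the 18.9-nm display
   pixel); luminal voxels carry an intensity density α per nm of depth and
   are summed axially.
3. **Imaging** — the projection is area-averaged down to 18.9-nm pixels,
   convolved with a radially symmetric Lorentzian PSF (FWHM 50 nm), and
   offset by a uniform background.  The result is the expected photon
   count per pixel.
4. **Noise** — shot noise is added by sampling a Poisson distribution per
   pixel with the expected image as its mean.

Defaults (t = 50 nm, α = 10, background = 1, Γ = 50 nm, 25 holes per
image, 4 images per diameter over the 30–200 nm sweep) emulate the
signal-to-noise of live-cell STED acquisitions of luminally labeled ER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .io import PixelImage
from .psf import lorentzian_2d_kernel
from .tubules import TubuleGeometry, chord_projection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "LuminalVolume",
    "build_hole_volume",
    "render_image",
    "add_shot_noise",
    "simulate_hole_field",
    "hole_field_sweep",
    "ground_truth_only",
    "sweep_ground_truth",
    "simulate_tubule_image",
    "alpha_for_peak",
    "sheet_intensity_ratio",
    "thickness_from_ratio",
    "SWEEP_DIAMETERS_NM",
]

#: inner-diameter sweep simulated in the benchmark (nm)
SWEEP_DIAMETERS_NM = (30.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0)


@dataclass(frozen=True)
class SimulationConfig:
    sheet_thickness_nm: float = 50.0
    hole_inner_diameter_nm: float = 100.0
    n_holes: int = 25
    hole_spacing_px: float = 105.0  # curved edge to curved edge
    lateral_px_nm: float = 18.9
    axial_voxel_nm: float = 1.0
    psf_fwhm_nm: float = 50.0
    alpha: float = 10.0  # intensity per nm of luminal depth (per voxel at 1-nm voxels)
    background: float = 1.0
    jitter: bool = True
    supersample: int = 9
    margin_px: int = 30

    def __post_init__(self) -> None:
        for name in ("sheet_thickness_nm", "hole_inner_diameter_nm", "lateral_px_nm", "axial_voxel_nm", "psf_fwhm_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.n_holes < 0:
            raise ValueError("n_holes must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def rim_tube_radius_nm(self) -> float:
        return self.sheet_thickness_nm / 2.0

    @property
    def hole_outer_radius_nm(self) -> float:
        """Lateral extent of the curved rim: torus centerline radius."""
        return self.hole_inner_diameter_nm / 2.0 + self.rim_tube_radius_nm

    @property
    def fine_px_nm(self) -> float:
        return self.lateral_px_nm / self.supersample


@dataclass(frozen=True)
class GroundTruth:
    """True geometry of one simulated image, in package pixel conventions."""

    pixel_size_nm: float
    centers_px: np.ndarray = field(repr=False)  # (n, 2) fractional (row, col)
    inner_diameters_nm: np.ndarray = field(repr=False)
    sheet_rect_px: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # r0, r1, c0, c1
    tubule_axis_row_px: float | None = None
    tubule_diameter_nm: float | None = None
    labeling: str | None = None

    @property
    def centers_nm(self) -> np.ndarray:
        return (self.centers_px + 0.5) * self.pixel_size_nm


@dataclass(frozen=True)
class LuminalVolume:
    """Luminal occupancy on the fine lateral grid, stored column-wise.

    ``column_counts[i, j]`` is the number of 1-nm (``axial_voxel_nm``)
    voxels that are luminal in fine column (i, j); the explicit 3D grid is
    never materialized.  ``depth_nm`` is the luminal path length per
    column.
    """

    column_counts: np.ndarray = field(repr=False)
    axial_voxel_nm: float
    fine_px_nm: float
    supersample: int

    @property
    def depth_nm(self) -> np.ndarray:
        return self.column_counts * self.axial_voxel_nm

    @property
    def luminal_voxel_count(self) -> int:
        return int(self.column_counts.sum())


def _band_voxel_counts(total_thickness_nm: float, half_height_nm: np.ndarray, dz: float) -> np.ndarray:
    """Voxels (z centers) inside a band of half-height h centered mid-slab."""
    t = total_thickness_nm
    h = np.asarray(half_height_nm, dtype=float)
    lo = t / 2.0 - h
    hi = t / 2.0 + h
    # z centers are (k + 0.5)·dz, k = 0..nz−1
    k_lo = np.ceil(lo / dz - 0.5)
    k_hi = np.floor(hi / dz - 0.5)
    nz = int(round(t / dz))
    k_lo = np.clip(k_lo, 0, nz)
    k_hi = np.clip(k_hi, -1, nz - 1)
    return np.maximum(k_hi - k_lo + 1, 0).astype(np.int32)


def _field_layout(config: SimulationConfig) -> tuple[int, int, float, float]:
    """(image pixels per side, grid side, center spacing nm, sheet margin nm)."""
    g = int(math.ceil(math.sqrt(max(config.n_holes, 1))))
    spacing_nm = config.hole_spacing_px * config.lateral_px_nm + 2.0 * config.hole_outer_radius_nm
    sheet_nm = g * spacing_nm
    sheet_px = int(math.ceil(sheet_nm / config.lateral_px_nm))
    n_px = sheet_px + 2 * config.margin_px
    return n_px, g, spacing_nm, config.margin_px * config.lateral_px_nm


def _hole_centers(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Jittered grid of hole centers (nm); the sole jitter RNG consumer."""
    _, g, spacing_nm, margin_nm = _field_layout(config)
    centers = []
    jitter_half = 0.5 * config.lateral_px_nm
    for k in range(config.n_holes):
        gi, gj = divmod(k, g)
        cy = margin_nm + (gi + 0.5) * spacing_nm
        cx = margin_nm + (gj + 0.5) * spacing_nm
        if config.jitter:
            cy += rng.uniform(-jitter_half, jitter_half)
            cx += rng.uniform(-jitter_half, jitter_half)
        centers.append((cy, cx))
    return centers


def ground_truth_only(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> GroundTruth:
    """The ground truth :func:`simulate_hole_field` would emit, without rendering.

    Consumes the RNG identically to the geometry stage, so the same seed
    yields bit-identical hole centers.
    """
    rng = np.random.default_rng(rng)
    n_px, g, spacing_nm, margin_nm = _field_layout(config)
    centers_nm = _hole_centers(config, rng)
    p = config.lateral_px_nm
    sheet_lo = margin_nm
    sheet_hi = n_px * p - margin_nm
    centers_px = np.asarray([(cy / p - 0.5, cx / p - 0.5) for cy, cx in centers_nm], dtype=float).reshape(-1, 2)
    return GroundTruth(
        pixel_size_nm=p,
        centers_px=centers_px,
        inner_diameters_nm=np.full(len(centers_nm), config.hole_inner_diameter_nm),
        sheet_rect_px=(sheet_lo / p - 0.5, sheet_hi / p - 0.5, sheet_lo / p - 0.5, sheet_hi / p - 0.5),
    )


def sweep_ground_truth(
    config: SimulationConfig | None = None,
    diameters_nm: tuple[float, ...] = SWEEP_DIAMETERS_NM,
    images_per_diameter: int = 4,
    base_seed: int = 0,
) -> list[GroundTruth]:
    """Ground truths of the full benchmark sweep, skipping the rendering."""
    config = config or SimulationConfig()
    seeds = np.random.SeedSequence(base_seed).spawn(len(diameters_nm) * images_per_diameter)
    truths = []
    k = 0
    for d in diameters_nm:
        cfg = replace(config, hole_inner_diameter_nm=float(d))
        for _ in range(images_per_diameter):
            truths.append(ground_truth_only(cfg, np.random.default_rng(seeds[k])))
            k += 1
    return truths


def build_hole_volume(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> tuple[LuminalVolume, GroundTruth]:
    """Luminal occupancy of a hole-perforated slab plus its ground truth.

    Holes are laid out on a jittered square grid inside a rectangular sheet
    footprint surrounded by a background margin.  Raises if the requested
    spacing makes rims overlap.
    """
    rng = np.random.default_rng(rng)
    n_px, g, spacing_nm, margin_nm = _field_layout(config)
    if config.n_holes > 0 and spacing_nm < 2.0 * config.hole_outer_radius_nm:
        raise ValueError("holes overlap at the requested spacing")

    s = config.supersample
    fine = config.fine_px_nm
    n_fine = n_px * s
    dz = config.axial_voxel_nm
    nz = int(round(config.sheet_thickness_nm / dz))

    counts = np.zeros((n_fine, n_fine), dtype=np.int32)
    # sheet footprint (nm) — margin of empty background on every side
    sheet_lo = margin_nm
    sheet_hi = n_px * config.lateral_px_nm - margin_nm
    lo_idx = int(math.ceil(sheet_lo / fine - 0.5))
    hi_idx = int(math.floor(sheet_hi / fine - 0.5))
    counts[lo_idx : hi_idx + 1, lo_idx : hi_idx + 1] = nz

    centers_nm = _hole_centers(config, rng)

    r_tube = config.rim_tube_radius_nm
    r_center = config.hole_outer_radius_nm
    a_inner = config.hole_inner_diameter_nm / 2.0
    patch_half = int(math.ceil((r_center + fine) / fine)) + 1

    fine_coord = (np.arange(n_fine) + 0.5) * fine
    for cy, cx in centers_nm:
        ci = int(round(cy / fine - 0.5))
        cj = int(round(cx / fine - 0.5))
        i0, i1 = max(ci - patch_half, 0), min(ci + patch_half + 1, n_fine)
        j0, j1 = max(cj - patch_half, 0), min(cj + patch_half + 1, n_fine)
        yy = fine_coord[i0:i1, None] - cy
        xx = fine_coord[None, j0:j1] - cx
        rho = np.hypot(yy, xx)
        patch = counts[i0:i1, j0:j1]
        patch[rho <= a_inner] = 0
        rim = (rho > a_inner) & (rho <= r_center)
        if np.any(rim):
            h = np.sqrt(np.clip(r_tube**2 - (r_center - rho[rim]) ** 2, 0.0, None))
            excl = _band_voxel_counts(config.sheet_thickness_nm, h, dz)
            patch[rim] = np.maximum(patch[rim] - excl, 0)

    p = config.lateral_px_nm
    centers_px = np.asarray([(cy / p - 0.5, cx / p - 0.5) for cy, cx in centers_nm], dtype=float).reshape(-1, 2)
    truth = GroundTruth(
        pixel_size_nm=p,
        centers_px=centers_px,
        inner_diameters_nm=np.full(len(centers_nm), config.hole_inner_diameter_nm),
        sheet_rect_px=(sheet_lo / p - 0.5, sheet_hi / p - 0.5, sheet_lo / p - 0.5, sheet_hi / p - 0.5),
    )
    volume = LuminalVolume(column_counts=counts, axial_voxel_nm=dz, fine_px_nm=fine, supersample=s)
    return volume, truth


def render_image(volume: LuminalVolume, config: SimulationConfig) -> PixelImage:
    """Noise-free expected image: project → downsample → blur → + background."""
    s = volume.supersample
    proj = volume.depth_nm * config.alpha  # axial sum of α-filled voxels
    n_fine = proj.shape[0]
    n_px = n_fine // s
    binned = proj[: n_px * s, : n_px * s].reshape(n_px, s, n_px, s).mean(axis=(1, 3))

    kernel = lorentzian_2d_kernel(config.psf_fwhm_nm, config.lateral_px_nm)
    pad = kernel.shape[0] // 2
    padded = np.pad(binned, pad, mode="reflect")
    blurred = fftconvolve(padded, kernel, mode="valid")
    expected = np.clip(blurred, 0.0, None) + config.background
    return PixelImage(values=expected, pixel_size_nm=config.lateral_px_nm)


def add_shot_noise(expected: PixelImage, rng: np.random.Generator | int | None = None) -> PixelImage:
    """Per-pixel Poisson draw with the expected image as the mean."""
    if np.any(expected.values < 0):
        raise ValueError("expected values must be non-negative")
    rng = np.random.default_rng(rng)
    noisy = rng.poisson(expected.values).astype(np.int32)
    return expected.with_values(noisy)


def simulate_hole_field(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    return_expected: bool = False,
):
    """One noisy nanohole-field image with ground truth (jitter + shot noise)."""
    rng = np.random.default_rng(rng)
    volume, truth = build_hole_volume(config, rng)
    expected = render_image(volume, config)
    noisy = add_shot_noise(expected, rng)
    if return_expected:
        return noisy, truth, expected
    return noisy, truth


def hole_field_sweep(
    config: SimulationConfig | None = None,
    diameters_nm: tuple[float, ...] = SWEEP_DIAMETERS_NM,
    images_per_diameter: int = 4,
    base_seed: int = 0,
):
    """The benchmark sweep: ``images_per_diameter`` fields per inner diameter.

    Yields ``(inner_diameter_nm, replicate_index, noisy_image, ground_truth)``
    with per-image RNG streams spawned deterministically from ``base_seed``.
    """
    config = config or SimulationConfig()
    seeds = np.random.SeedSequence(base_seed).spawn(len(diameters_nm) * images_per_diameter)
    k = 0
    for d in diameters_nm:
        cfg = replace(config, hole_inner_diameter_nm=float(d))
        for rep in range(images_per_diameter):
            image, truth = simulate_hole_field(cfg, np.random.default_rng(seeds[k]))
            k += 1
            yield d, rep, image, truth


def _tubule_volume(diameter_nm: float, geometry: TubuleGeometry, config: SimulationConfig, n_px: int, axis_row_nm: float) -> LuminalVolume:
    """Straight horizontal tubule: label occupancy per fine column."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    s = config.supersample
    fine = config.fine_px_nm
    n_fine = n_px * s
    dz = config.axial_voxel_nm
    a_o = diameter_nm / 2.0
    # the tubule's own axial extent, not the sheet thickness
    thickness = diameter_nm
    y = (np.arange(n_fine) + 0.5) * fine - axis_row_nm
    h_o = np.sqrt(np.clip(a_o**2 - y**2, 0.0, None))
    counts_o = _band_voxel_counts(thickness, h_o, dz)
    if geometry.labeling == "lumen":
        col = counts_o
    else:
        a_i = a_o - geometry.annulus_thickness_nm
        if a_i < 0:
            raise ValueError("annulus thicker than the tubule radius")
        h_i = np.sqrt(np.clip(a_i**2 - y**2, 0.0, None))
        col = counts_o - _band_voxel_counts(thickness, h_i, dz)
    counts = np.repeat(col[:, None], n_fine, axis=1).astype(np.int32)
    return LuminalVolume(column_counts=counts, axial_voxel_nm=dz, fine_px_nm=fine, supersample=s)


def simulate_tubule_image(
    diameter_nm: float,
    geometry: TubuleGeometry,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_px: int = 64,
    return_expected: bool = False,
):
    """Noisy image of a straight tubule crossing the field horizontally.

    The axis row is jittered within ±0.5 pixel of the image center when
    ``config.jitter`` is set.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(rng)
    axis_row_nm = n_px / 2.0 * config.lateral_px_nm
    if config.jitter:
        axis_row_nm += rng.uniform(-0.5, 0.5) * config.lateral_px_nm
    volume = _tubule_volume(diameter_nm, geometry, config, n_px, axis_row_nm)
    expected = render_image(volume, config)
    noisy = add_shot_noise(expected, rng)
    truth = GroundTruth(
        pixel_size_nm=config.lateral_px_nm,
        centers_px=np.empty((0, 2)),
        inner_diameters_nm=np.empty(0),
        tubule_axis_row_px=axis_row_nm / config.lateral_px_nm - 0.5,
        tubule_diameter_nm=diameter_nm,
        labeling=geometry.labeling,
    )
    if return_expected:
        return noisy, truth, expected
    return noisy, truth


def _noiseless_tubule_peak(diameter_nm: float, geometry: TubuleGeometry, config: SimulationConfig, n_px: int = 65) -> float:
    # odd field: the axis sits on a pixel center, so the sampled peak is
    # the true profile maximum rather than a half-pixel-offset average
    axis_row_nm = n_px / 2.0 * config.lateral_px_nm
    volume = _tubule_volume(diameter_nm, geometry, config, n_px, axis_row_nm)
    expected = render_image(volume, config)
    return float(expected.values.max() - config.background)


def alpha_for_peak(
    target_peak: float,
    diameter_nm: float,
    geometry: TubuleGeometry,
    config: SimulationConfig | None = None,
) -> float:
    """α that makes the noiseless tubule peak (above background) ≈ target.

    Rendering is linear in α, so one reference render suffices.
    """
    config = config or SimulationConfig()
    ref = _noiseless_tubule_peak(diameter_nm, geometry, config)
    if ref <= 0:
        raise ValueError("reference render has no signal")
    return config.alpha * (target_peak - config.background) / ref


def sheet_intensity_ratio(
    thickness_nm: float,
    tubule_diameter_nm: float,
    config: SimulationConfig | None = None,
) -> float:
    """Expected sheet-interior / tubule-peak intensity ratio (background-subtracted).

    A luminal marker's signal is proportional to the luminal path length,
    so a slab of thickness t yields interior intensity α·t while a tubule
    peaks below α·d after blurring; the ratio rises monotonically with
    sheet thickness and can be inverted to estimate thickness from images.
    """
    if thickness_nm < 0:
        raise ValueError("thickness must be >= 0")
    config = config or SimulationConfig()
    if thickness_nm == 0:
        return 0.0
    sheet_signal = config.alpha * thickness_nm  # blur of a constant is the constant
    lumen = TubuleGeometry(labeling="lumen")
    tubule_peak = _noiseless_tubule_peak(tubule_diameter_nm, lumen, config)
    return sheet_signal / tubule_peak


def thickness_from_ratio(
    ratio: float,
    tubule_diameter_nm: float,
    config: SimulationConfig | None = None,
    thickness_grid_nm: np.ndarray | None = None,
) -> float:
    """Invert :func:`sheet_intensity_ratio` by monotone lookup."""
    config = config or SimulationConfig()
    grid = thickness_grid_nm if thickness_grid_nm is not None else np.linspace(0.0, 150.0, 76)
    ratios = [sheet_intensity_ratio(float(t), tubule_diameter_nm, config) for t in grid]
    return float(np.interp(ratio, ratios, grid))
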