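"""Semiautomated nanohole detection and border delimitation.

The detection chain mirrors the analysis applied to live-cell STED images:

1. smooth the raw image slightly (Gaussian, σ = 1 px);
2. find candidate hole centers as local intensity minima with a minimum
   separation of 4 px;
3. build a binary ER mask by max-normalizing, median filtering with a
   15×15 kernel, and thresholding at 5% of the maximum;
4. marker-controlled watershed of the masked, smoothed image with the
   candidates as markers;
5. within each selected watershed region, define the *hole depth* as the
   mean smoothed intensity of the region's edge pixels minus the region
   minimum, and take the pixels below ``minimum + 0.4·depth`` as the hole.

Hole selection is semiautomated: all minima seed the watershed, and user
seed points (interactive in the original workflow; CSV here) pick which
regions are analyzed.  Automatic rejection rules (border contact, too few
hole pixels, zero depth) plus an optional manual rejection list complete
the selection.

Connectivity is 8-neighborhood for regions, edges, and flooding.  A
connected minimum plateau contributes a single seed at its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.segmentation import watershed as _sk_watershed

from .io import PixelImage, gaussian_smooth

__all__ = [
    "SeedPoint",
    "ERMask",
    "HoleRegion",
    "find_local_minima",
    "er_mask",
    "watershed_segment",
    "delimit_hole",
    "select_and_reject",
    "segment_holes",
    "read_seed_points",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedPoint:
    row: int
    col: int
    source: str = "auto_minimum"  # or "user"


@dataclass(frozen=True)
class ERMask:
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class HoleRegion:
    """One watershed region with its 40%-depth hole delimitation."""

    label_id: int
    watershed_pixels: np.ndarray = field(repr=False)  # (n, 2) row, col
    edge_pixels: np.ndarray = field(repr=False)
    hole_pixels: np.ndarray = field(repr=False)
    raw_hole_values: np.ndarray = field(repr=False)
    min_value: float = np.nan
    edge_mean: float = np.nan
    depth: float = np.nan
    border_threshold: float = np.nan
    measurable: bool = True
    rejected: bool = False
    rejection_reason: str = ""


def read_seed_points(path, frame: int | None = None) -> list[SeedPoint]:
    """User-picked hole centers from CSV with columns row, col [, frame]."""
    import pandas as pd

    table = pd.read_csv(path)
    if not {"row", "col"} <= set(table.columns):
        raise ValueError("seed CSV requires 'row' and 'col' columns")
    if frame is not None and "frame" in table.columns:
        table = table[table["frame"] == frame]
    return [SeedPoint(int(r), int(c), source="user") for r, c in zip(table["row"], table["col"])]


def _euclidean_footprint(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dy**2 + dx**2 < radius**2


def find_local_minima(
    smoothed: PixelImage,
    mask: ERMask,
    min_separation_px: float = 4.0,
) -> list[SeedPoint]:
    """Local minima inside the mask, at least ``min_separation_px`` apart.

    A connected equal-valued plateau that is a minimum contributes one
    candidate at its centroid (rounded to the nearest pixel).  When two
    candidates conflict on separation the deeper (lower-valued) one wins.
    Returned in row-major order.
    """
    values = np.asarray(smoothed.values, dtype=float)
    m = mask.mask
    if m.shape != values.shape:
        raise ValueError("mask shape must match image shape")
    if not m.any():
        return []

    # regional minima: plateaus with no lower 8-neighbor (a flat shelf
    # draining to lower ground is not a minimum)
    local_min = morphology.local_minima(values, connectivity=2)
    local_min &= m

    # collapse minimum plateaus to their centroids
    lab, n_lab = ndimage.label(local_min, structure=_EIGHT)
    if n_lab == 0:
        return []
    centroids = ndimage.center_of_mass(local_min, lab, np.arange(1, n_lab + 1))
    cand = [(values[int(round(r))][int(round(c))], int(round(r)), int(round(c))) for r, c in centroids]

    # greedy keep-deeper conflict resolution: accept in depth order, each
    # acceptance blocking a separation disk around itself
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    blocked = np.zeros(values.shape, dtype=bool)
    disk = np.argwhere(_euclidean_footprint(min_separation_px)) - int(np.ceil(min_separation_px))
    kept: list[tuple[int, int]] = []
    n_rows, n_cols = values.shape
    for _, r, c in cand:
        if blocked[r, c]:
            continue
        kept.append((r, c))
        rows = np.clip(r + disk[:, 0], 0, n_rows - 1)
        cols = np.clip(c + disk[:, 1], 0, n_cols - 1)
        blocked[rows, cols] = True
    kept.sort()
    return [SeedPoint(row=r, col=c) for r, c in kept]


def er_mask(
    image: PixelImage,
    median_kernel_px: int = 15,
    threshold_fraction: float = 0.05,
) -> ERMask:
    """Binary ER footprint: max-normalize, median filter, threshold.

    Deterministic; raises on an all-zero image.
    """
    values = np.asarray(image.values, dtype=float)
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("no signal: image maximum is zero")
    normalized = values / vmax
    filtered = ndimage.median_filter(normalized, size=median_kernel_px, mode="mirror")
    return ERMask(mask=filtered >= threshold_fraction)


def watershed_segment(smoothed: PixelImage, seeds: list[SeedPoint], mask: ERMask) -> np.ndarray:
    """Marker-controlled watershed of the masked, smoothed intensity landscape.

    Each seed floods its catchment basin by ascending intensity
    (8-connectivity); label ``k+1`` corresponds to ``seeds[k]``.  Unmasked
    pixels stay 0.
    """
    if not seeds:
        raise ValueError("watershed requires at least one seed")
    values = np.asarray(smoothed.values, dtype=float)
    markers = np.zeros(values.shape, dtype=np.int32)
    for i, seed in enumerate(seeds, start=1):
        if not (0 <= seed.row < values.shape[0] and 0 <= seed.col < values.shape[1]):
            raise ValueError(f"seed {seed} outside image bounds")
        markers[seed.row, seed.col] = i
    return _sk_watershed(values, markers=markers, mask=mask.mask, connectivity=2)


def delimit_hole(
    region_pixels: np.ndarray,
    smoothed: PixelImage,
    raw: PixelImage | None = None,
    depth_fraction: float = 0.4,
    label_id: int = 0,
) -> HoleRegion:
    """Apply the 40%-depth rule within one watershed region.

    Edge pixels are the region's own pixels 8-adjacent to a pixel outside
    the region (inner boundary).  Depth = mean(edge) − min(region) on the
    smoothed image; hole pixels are those strictly below
    ``min + depth_fraction·depth``.  Raw-image values at the hole pixels
    are carried for downstream quantification.  A flat region (depth ≤ 0)
    is flagged unmeasurable.
    """
    region_pixels = np.atleast_2d(np.asarray(region_pixels, dtype=int))
    if region_pixels.size == 0:
        raise ValueError("empty region")
    values = np.asarray(smoothed.values, dtype=float)
    raw_values = np.asarray((raw or smoothed).values, dtype=float)

    in_region = np.zeros(values.shape, dtype=bool)
    in_region[region_pixels[:, 0], region_pixels[:, 1]] = True
    interior = ndimage.binary_erosion(in_region, structure=_EIGHT, border_value=0)
    edge_mask = in_region & ~interior
    edge_pixels = np.argwhere(edge_mask)

    region_values = values[region_pixels[:, 0], region_pixels[:, 1]]
    min_value = float(region_values.min())
    edge_mean = float(values[edge_mask].mean())
    depth = edge_mean - min_value
    if depth <= 0:
        return HoleRegion(
            label_id=label_id,
            watershed_pixels=region_pixels,
            edge_pixels=edge_pixels,
            hole_pixels=np.empty((0, 2), dtype=int),
            raw_hole_values=np.empty(0),
            min_value=min_value,
            edge_mean=edge_mean,
            depth=depth,
            border_threshold=min_value,
            measurable=False,
        )

    border_threshold = min_value + depth_fraction * depth
    below = region_values < border_threshold  # strict: ties at the threshold excluded
    hole_pixels = region_pixels[below]
    return HoleRegion(
        label_id=label_id,
        watershed_pixels=region_pixels,
        edge_pixels=edge_pixels,
        hole_pixels=hole_pixels,
        raw_hole_values=raw_values[hole_pixels[:, 0], hole_pixels[:, 1]],
        min_value=min_value,
        edge_mean=edge_mean,
        depth=depth,
        border_threshold=border_threshold,
        measurable=True,
    )


def select_and_reject(
    labels: np.ndarray,
    user_points: list[SeedPoint] | np.ndarray,
    smoothed: PixelImage,
    raw: PixelImage | None = None,
    depth_fraction: float = 0.4,
    min_hole_pixels: int = 3,
    manual_reject_labels: set[int] | None = None,
) -> tuple[list[HoleRegion], list[str]]:
    """Keep user-selected watershed regions and apply rejection rules.

    Rules: region touches the image border → "border"; hole has fewer than
    ``min_hole_pixels`` pixels → "too_small"; flat region → "no_depth";
    label on the manual rejection list → "manual".  Returns accepted
    regions (rejected ones are kept with their reason flagged) plus notes
    for user points that fell outside any region.
    """
    labels = np.asarray(labels)
    manual_reject_labels = manual_reject_labels or set()
    notes: list[str] = []
    chosen: dict[int, SeedPoint] = {}
    for pt in user_points:
        row, col = (pt.row, pt.col) if isinstance(pt, SeedPoint) else (int(pt[0]), int(pt[1]))
        if not (0 <= row < labels.shape[0] and 0 <= col < labels.shape[1]) or labels[row, col] == 0:
            notes.append(f"user point ({row}, {col}) outside any segmented region; skipped")
            continue
        chosen.setdefault(int(labels[row, col]), SeedPoint(row, col, source="user"))

    regions: list[HoleRegion] = []
    n_rows, n_cols = labels.shape
    for label_id in sorted(chosen):
        pixels = np.argwhere(labels == label_id)
        hole = delimit_hole(pixels, smoothed, raw=raw, depth_fraction=depth_fraction, label_id=label_id)
        reason = ""
        if label_id in manual_reject_labels:
            reason = "manual"
        elif (pixels[:, 0].min() == 0 or pixels[:, 1].min() == 0
              or pixels[:, 0].max() == n_rows - 1 or pixels[:, 1].max() == n_cols - 1):
            reason = "border"
        elif not hole.measurable:
            reason = "no_depth"
        elif hole.hole_pixels.shape[0] < min_hole_pixels:
            reason = "too_small"
        if reason:
            hole = HoleRegion(
                **{**hole.__dict__, "rejected": True, "rejection_reason": reason}
            )
        regions.append(hole)
    return regions, notes


def segment_holes(
    raw: PixelImage,
    user_points: list[SeedPoint] | np.ndarray,
    sigma_px: float = 1.0,
    min_separation_px: float = 4.0,
    depth_fraction: float = 0.4,
    min_hole_pixels: int = 3,
) -> tuple[list[HoleRegion], list[str]]:
    """Full chain: smooth → mask → minima → watershed → delimit → select."""
    smoothed = gaussian_smooth(raw, sigma_px)
    mask = er_mask(raw)
    seeds = find_local_minima(smoothed, mask, min_separation_px)
    if not seeds:
        return [], ["no candidate minima found"]
    labels = watershed_segment(smoothed, seeds, mask)
    return select_and_reject(
        labels,
        user_points,
        smoothed,
        raw=raw,
        depth_fraction=depth_fraction,
        min_hole_pixels=min_hole_pixels,
    )
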