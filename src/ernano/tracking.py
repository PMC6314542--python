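"""Seeded nanohole tracking across time-lapse frames.

Nanoholes move in the plane of the sheet, so a track follows the *deepest
local intensity minimum* within a search disk of the previous position —
the "local minimum center correction" applied frame by frame.  Presence in
a frame requires the minimum to be genuinely deep relative to its local
surround (a fraction of the start-frame contrast), which separates a
disappearing hole from shot noise.  Single-frame dropouts are tolerated
(configurable gap), as they are plausible at 70-ms framing.

Input stacks are expected to be preprocessed as in the analysis chain
(bleach-corrected, then Gaussian-smoothed with σ = 1 px); see
:func:`preprocess_stack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageStack, bleach_correct, gaussian_smooth
from .segmentation import SeedPoint

__all__ = ["Track", "preprocess_stack", "track_hole", "classify_persistence", "PersistenceSummary"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Track:
    """Per-frame positions of one seeded hole; ``None`` marks absence."""

    seed: SeedPoint
    start_frame: int
    positions: tuple[tuple[int, int] | None, ...]
    search_radius_px: float
    status: str = ""

    @property
    def present(self) -> np.ndarray:
        return np.array([p is not None for p in self.positions])


def preprocess_stack(stack: ImageStack, reference_frame_index: int = 0, sigma_px: float = 1.0) -> ImageStack:
    """Bleach-correct then smooth every frame (the tracking input chain)."""
    corrected = bleach_correct(stack, reference_frame_index) if len(stack) > 1 else stack
    frames = tuple(gaussian_smooth(f, sigma_px) for f in corrected.frames)
    return ImageStack(frames=frames, frame_interval_s=stack.frame_interval_s)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _deepest_minimum(values: np.ndarray, local_min: np.ndarray, center: tuple[int, int], radius: float):
    """Deepest local minimum within the search disk, or None."""
    offsets = _disk_offsets(radius)
    rows = center[0] + offsets[:, 0]
    cols = center[1] + offsets[:, 1]
    ok = (rows >= 0) & (rows < values.shape[0]) & (cols >= 0) & (cols < values.shape[1])
    rows, cols = rows[ok], cols[ok]
    is_min = local_min[rows, cols]
    if not is_min.any():
        return None
    rows, cols = rows[is_min], cols[is_min]
    k = int(np.argmin(values[rows, cols]))
    return int(rows[k]), int(cols[k])


def _local_depth(values: np.ndarray, position: tuple[int, int], radius: float) -> float:
    """Minimum-to-surround contrast: mean over a ring just outside the disk."""
    r_out = radius + 2.0
    offsets = _disk_offsets(r_out)
    d2 = offsets[:, 0] ** 2 + offsets[:, 1] ** 2
    ring = offsets[(d2 > radius**2)]
    rows = position[0] + ring[:, 0]
    cols = position[1] + ring[:, 1]
    ok = (rows >= 0) & (rows < values.shape[0]) & (cols >= 0) & (cols < values.shape[1])
    if not ok.any():
        return 0.0
    surround = float(values[rows[ok], cols[ok]].mean())
    return surround - float(values[position])


def track_hole(
    stack: ImageStack,
    seed: SeedPoint,
    search_radius_px: float = 5.0,
    depth_min_fraction: float = 0.2,
    start_frame: int = 0,
    gap_frames: int = 1,
) -> Track:
    """Follow one hole from ``start_frame`` to the end of the stack.

    Each frame snaps to the deepest qualifying local minimum within
    ``search_radius_px`` of the last known position.  A minimum qualifies
    when its surround-to-minimum contrast is at least ``depth_min_fraction``
    of the contrast measured at the snapped seed in the start frame.
    After more than ``gap_frames`` consecutive absent frames the track
    ends (remaining frames are absent).
    """
    frames = [np.asarray(f.values, dtype=float) for f in stack.frames]
    minima = [v == ndimage.minimum_filter(v, footprint=_EIGHT, mode="mirror") for v in frames]

    first = _deepest_minimum(frames[start_frame], minima[start_frame], (seed.row, seed.col), search_radius_px)
    if first is None:
        raise ValueError(f"no hole at seed ({seed.row}, {seed.col}) in frame {start_frame}")
    depth_ref = _local_depth(frames[start_frame], first, search_radius_px)
    if depth_ref <= 0:
        raise ValueError(f"no hole at seed ({seed.row}, {seed.col}): zero start-frame depth")
    depth_min = depth_min_fraction * depth_ref

    positions: list[tuple[int, int] | None] = [None] * start_frame + [first]
    last = first
    missing = 0
    ended = False
    for t in range(start_frame + 1, len(frames)):
        if ended:
            positions.append(None)
            continue
        hit = _deepest_minimum(frames[t], minima[t], last, search_radius_px)
        if hit is not None and _local_depth(frames[t], hit, search_radius_px) >= depth_min:
            positions.append(hit)
            last = hit
            missing = 0
        else:
            positions.append(None)
            missing += 1
            if missing > gap_frames:
                ended = True
    track = Track(
        seed=seed,
        start_frame=start_frame,
        positions=tuple(positions),
        search_radius_px=search_radius_px,
    )
    return _with_status(track, len(frames))


def _with_status(track: Track, n_frames: int) -> Track:
    present = track.present
    if not present.any():
        status = "never_present"
    else:
        at_start = bool(present[0])
        at_end = bool(present[-1])
        if at_start and at_end:
            status = "persisted"
        elif not at_start and at_end:
            status = "appeared"
        elif at_start and not at_end:
            status = "disappeared"
        else:
            status = "appeared_and_disappeared"
    return Track(
        seed=track.seed,
        start_frame=track.start_frame,
        positions=track.positions,
        search_radius_px=track.search_radius_px,
        status=status,
    )


@dataclass(frozen=True)
class PersistenceSummary:
    n_tracks: int
    fractions: dict = field(default_factory=dict)  # status -> fraction; sums to 1


def classify_persistence(tracks: list[Track], n_frames: int) -> tuple[list[Track], PersistenceSummary]:
    """Assign persistence status per track and summarize the cohort.

    persisted = present in the first and last frame; appeared = absent at
    start, present at end; disappeared = the reverse; both-ends absent with
    an interior presence run = appeared_and_disappeared.  Fractions
    partition the classified tracks.
    """
    if not tracks:
        raise ValueError("no tracks to classify")
    classified = [_with_status(t, n_frames) for t in tracks]
    statuses = [t.status for t in classified if t.status != "never_present"]
    if not statuses:
        raise ValueError("no track was ever present")
    order = ["persisted", "appeared", "disappeared", "appeared_and_disappeared"]
    fractions = {s: statuses.count(s) / len(statuses) for s in order}
    return classified, PersistenceSummary(n_tracks=len(statuses), fractions=fractions)
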