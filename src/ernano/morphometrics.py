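"""Per-hole shape statistics and between-condition comparisons.

A segmented hole is a set of pixels.  Two scalar descriptors are computed:

* the *equivalent diameter* ``d = 2·√(A/π)``, the diameter of the circle
  whose area equals the hole's pixel area ``A = n·p²``;
* the *symmetry* ``s = √(λ2/λ1)``, the ratio of the standard deviations of
  the pixel positions along the minor and major principal axes, where
  λ1 ≥ λ2 are the eigenvalues of the 2×2 covariance matrix of pixel-center
  coordinates.  ``s = 1`` for a circle; small ``s`` means elongated.

Covariance uses the population normalization (divide by n): a hole's pixel
set is a complete enumeration, not a sample.  A variance-ratio variant
(``λ2/λ1``) is available behind a flag.

Group comparisons follow the nonparametric route appropriate for these
skewed distributions: a Kruskal–Wallis omnibus test followed by Dunn's
pairwise z-tests with multiplicity adjustment.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HoleShape",
    "GroupComparison",
    "equivalent_diameter",
    "symmetry",
    "measure_hole",
    "compare_groups",
]


@dataclass(frozen=True)
class HoleShape:
    n_pixels: int
    area_nm2: float
    equivalent_diameter_nm: float
    symmetry: float
    lambda1: float  # larger covariance eigenvalue, px²
    lambda2: float  # smaller covariance eigenvalue, px²
    degenerate: bool = False


def equivalent_diameter(hole_pixels: np.ndarray, pixel_size_nm: float) -> float:
    """Diameter of the circle with the hole's area: ``2·√(n·p²/π)`` (nm)."""
    hole_pixels = np.atleast_2d(np.asarray(hole_pixels))
    if hole_pixels.size == 0:
        raise ValueError("empty pixel set has no equivalent diameter")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    area = hole_pixels.shape[0] * pixel_size_nm**2
    return 2.0 * math.sqrt(area / math.pi)


def _covariance_eigenvalues(coords: np.ndarray) -> tuple[float, float]:
    """Closed-form eigenvalues of the population covariance of 2D points."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    half_trace = 0.5 * (a + c)
    radius = math.sqrt(max(0.25 * (a - c) ** 2 + b**2, 0.0))
    lam1 = half_trace + radius
    lam2 = max(half_trace - radius, 0.0)
    return lam1, lam2


def symmetry(hole_pixels: np.ndarray, variance_ratio: bool = False) -> tuple[float, tuple[float, float]]:
    """Minor/major SD ratio ``√(λ2/λ1)`` of the pixel-position covariance.

    Rotation- and translation-invariant; exactly 1 for any pixel set
    invariant under a 90° grid rotation.  Collinear sets give 0 and a
    single pixel is undefined (both raise no error but are flagged via the
    returned eigenvalues: λ1 = 0 for a single pixel).

    With ``variance_ratio=True`` the unsquare-rooted ratio ``λ2/λ1`` is
    returned instead.
    """
    hole_pixels = np.atleast_2d(np.asarray(hole_pixels, dtype=float))
    if hole_pixels.shape[0] == 0:
        raise ValueError("empty pixel set has no symmetry")
    lam1, lam2 = _covariance_eigenvalues(hole_pixels)
    if lam1 <= 0:
        return float("nan"), (lam1, lam2)
    ratio = lam2 / lam1
    return (ratio if variance_ratio else math.sqrt(ratio)), (lam1, lam2)


def measure_hole(hole_pixels: np.ndarray, pixel_size_nm: float, variance_ratio: bool = False) -> HoleShape:
    """Bundle area, equivalent diameter, and symmetry for one hole."""
    hole_pixels = np.atleast_2d(np.asarray(hole_pixels))
    n = hole_pixels.shape[0]
    d = equivalent_diameter(hole_pixels, pixel_size_nm)
    s, (lam1, lam2) = symmetry(hole_pixels, variance_ratio=variance_ratio)
    return HoleShape(
        n_pixels=n,
        area_nm2=n * pixel_size_nm**2,
        equivalent_diameter_nm=d,
        symmetry=s,
        lambda1=lam1,
        lambda2=lam2,
        degenerate=not np.isfinite(s) or s == 0.0,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal–Wallis omnibus plus Dunn's pairwise post-hoc results."""

    conditions: tuple[str, ...]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)  # columns: a, b, z, p_raw, p_adj
    summary: pd.DataFrame = field(repr=False)  # per-condition n, median, iqr, q1, q3


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled mid-ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ),
    with the tie term T = Σ(t³ − t) / (12(N − 1)).
    """
    names = list(groups)
    pooled = np.concatenate([groups[name] for name in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name in names:
        size = groups[name].size
        mean_ranks[name] = ranks[start : start + size].mean()
        start += size

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(variance_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p_raw": p_raw, "p_adj": min(p_raw * n_pairs, 1.0)})
    return pd.DataFrame(rows)


def compare_groups(measurements_by_condition: dict[str, np.ndarray]) -> GroupComparison:
    """Kruskal–Wallis omnibus + Dunn's post hoc across ≥2 conditions.

    Conditions with fewer than two measurements are excluded with a
    warning.  Pairwise p-values are Bonferroni-adjusted over all pairs.
    """
    groups = {}
    for name, values in measurements_by_condition.items():
        values = np.asarray(values, dtype=float).ravel()
        if values.size < 2:
            warnings.warn(f"condition {name!r} has <2 measurements and is excluded", stacklevel=2)
            continue
        groups[name] = values
    if len(groups) < 2:
        raise ValueError("need at least two conditions with >=2 measurements each")

    h_stat, p_value = stats.kruskal(*groups.values())
    pairwise = _dunn_pairwise(groups)
    summary = pd.DataFrame(
        [
            {
                "condition": name,
                "n": values.size,
                "median": float(np.median(values)),
                "q1": float(np.percentile(values, 25)),
                "q3": float(np.percentile(values, 75)),
                "iqr": float(np.percentile(values, 75) - np.percentile(values, 25)),
            }
            for name, values in groups.items()
        ]
    )
    return GroupComparison(
        conditions=tuple(groups),
        h_statistic=float(h_stat),
        p_value=float(p_value),
        pairwise=pairwise,
        summary=summary,
    )
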