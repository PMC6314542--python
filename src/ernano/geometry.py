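"""Analytic curvature budget for an ER sheet with nanoholes and a tubule.

The model represents a patch of peripheral ER as a single disk-shaped sheet
of thickness ``t`` whose outer rim is the outer half of a torus (tube radius
``r = t/2``), perforated by ``n`` nanoholes whose curved edges are inner
half-tori, with a cylindrical tubule of variable length extending from the
rim.  Total membrane surface area is held fixed at that of a bare reference
disk (default 5 µm diameter): inserting holes or extending the tubule is
compensated by shrinking or growing the sheet disk.  The quantity of
interest is the fraction of the (fixed) surface area residing in curved
membrane — tubule wall, hole rims, and the sheet rim.

All lengths are nm and areas nm².  Curved area is reported without sign
decomposition: hole rims carry saddle curvature, but positive curvature that
does or does not carry orthogonal negative curvature is not distinguished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ERGeometryConfig",
    "CurvatureBudget",
    "hole_curved_area",
    "tubule_curved_area",
    "reference_total_area",
    "curvature_budget",
    "equivalent_tubule_length",
    "isoclines",
]


@dataclass(frozen=True)
class ERGeometryConfig:
    """Parameterization of the sheet + holes + tubule model.

    ``initial_sheet_diameter_nm`` sets the reference disk whose total surface
    area is conserved.  The rim tube radius is tied to the sheet thickness,
    ``r = t/2``, so the rim (and each hole rim) is tangent to both faces of
    the slab.
    """

    sheet_thickness_nm: float = 50.0
    initial_sheet_diameter_nm: float = 5000.0
    hole_inner_diameter_nm: float = 100.0
    tubule_diameter_nm: float = 100.0
    n_holes: int = 0
    tubule_length_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.sheet_thickness_nm <= 0:
            raise ValueError("sheet thickness must be positive")
        if self.hole_inner_diameter_nm <= 0:
            raise ValueError("hole inner diameter must be positive")
        if self.tubule_diameter_nm <= 0:
            raise ValueError("tubule diameter must be positive")
        if self.n_holes < 0:
            raise ValueError("n_holes must be >= 0")
        if self.tubule_length_nm < 0:
            raise ValueError("tubule length must be >= 0")
        if self.initial_sheet_diameter_nm <= self.sheet_thickness_nm:
            raise ValueError("sheet disk must be wider than its rim")

    @property
    def rim_tube_radius_nm(self) -> float:
        return self.sheet_thickness_nm / 2.0


@dataclass(frozen=True)
class CurvatureBudget:
    """Flat/curved decomposition of the fixed total surface area."""

    total_area_nm2: float
    flat_area_nm2: float
    curved_area_nm2: float
    adjusted_sheet_diameter_nm: float

    @property
    def curved_fraction(self) -> float:
        return self.curved_area_nm2 / self.total_area_nm2


def hole_curved_area(sheet_thickness_nm: float, hole_inner_diameter_nm: float) -> tuple[float, float]:
    """Curved area added and flat area removed by one nanohole.

    The hole edge is the inner half of a torus with tube radius ``r = t/2``
    and centerline radius ``R_h = inner radius + r`` (the torus equator sits
    at the stated inner diameter, and the rim is tangent to both slab
    faces).  Inner half-torus area is ``2π²·R_h·r − 4π·r²``; the hole also
    removes flat membrane from both faces of the slab out to the torus
    centerline, ``2·π·R_h²``.
    """
    t = float(sheet_thickness_nm)
    if t <= 0 or hole_inner_diameter_nm <= 0:
        raise ValueError("thickness and hole diameter must be positive")
    r = t / 2.0
    r_h = hole_inner_diameter_nm / 2.0 + r
    curved = 2.0 * math.pi**2 * r_h * r - 4.0 * math.pi * r**2
    flat_removed = 2.0 * math.pi * r_h**2
    return curved, flat_removed


def tubule_curved_area(tubule_diameter_nm: float, length_nm: float) -> float:
    """Lateral area of an open cylinder, ``π·d·L`` (no end cap)."""
    if tubule_diameter_nm <= 0:
        raise ValueError("tubule diameter must be positive")
    if length_nm < 0:
        raise ValueError("length must be >= 0")
    return math.pi * tubule_diameter_nm * length_nm


def _sheet_areas(rim_centerline_radius_nm: float, rim_tube_radius_nm: float) -> tuple[float, float]:
    """(flat, curved) area of a bare disk sheet with an outer half-torus rim.

    Flat membrane covers both faces out to the rim centerline; the rim
    contributes the outer half-torus, ``2π²·R·r + 4π·r²``.
    """
    big_r = rim_centerline_radius_nm
    r = rim_tube_radius_nm
    flat = 2.0 * math.pi * big_r**2
    curved = 2.0 * math.pi**2 * big_r * r + 4.0 * math.pi * r**2
    return flat, curved


def reference_total_area(config: ERGeometryConfig) -> float:
    """Surface area of the bare reference sheet (no holes, no tubule)."""
    r = config.rim_tube_radius_nm
    big_r = config.initial_sheet_diameter_nm / 2.0 - r
    flat, curved = _sheet_areas(big_r, r)
    return flat + curved


def curvature_budget(config: ERGeometryConfig) -> CurvatureBudget:
    """Flat/curved decomposition after inserting holes and extending a tubule.

    The sheet's rim-centerline radius ``R`` is solved in closed form
    (quadratic) so that the configuration's total surface area equals the
    bare reference sheet's.  The tubule joins the sheet at the rim and its
    junction removes curved rim area equal to the tubule's cross-section
    footprint (second-order; see methods note).

    Raises ``ValueError`` when no feasible sheet radius exists or the shrunk
    sheet cannot host the requested holes.
    """
    t = config.sheet_thickness_nm
    r = config.rim_tube_radius_nm
    a_ref = reference_total_area(config)

    curved_hole, flat_removed_hole = hole_curved_area(t, config.hole_inner_diameter_nm)
    tubule_area = tubule_curved_area(config.tubule_diameter_nm, config.tubule_length_nm)
    junction = (
        math.pi * (config.tubule_diameter_nm / 2.0) ** 2 if config.tubule_length_nm > 0 else 0.0
    )

    n = config.n_holes
    # total(R) = 2πR² + 2π²rR + 4πr² + n(curved_hole − flat_removed_hole)
    #            + tubule_area − junction  ==  a_ref
    c0 = (
        4.0 * math.pi * r**2
        + n * (curved_hole - flat_removed_hole)
        + tubule_area
        - junction
        - a_ref
    )
    # 2π R² + 2π² r R + c0 = 0
    disc = (2.0 * math.pi**2 * r) ** 2 - 4.0 * (2.0 * math.pi) * c0
    if disc < 0:
        raise ValueError("infeasible configuration: no sheet radius conserves the area")
    big_r = (-2.0 * math.pi**2 * r + math.sqrt(disc)) / (4.0 * math.pi)
    if big_r < r:
        raise ValueError("infeasible configuration: sheet shrinks below its rim radius")

    r_h = config.hole_inner_diameter_nm / 2.0 + r
    flat = 2.0 * math.pi * big_r**2 - n * flat_removed_hole
    if flat < 0 or n * r_h**2 > big_r**2:
        raise ValueError("infeasible configuration: holes exceed the sheet's flat area")

    curved = (
        2.0 * math.pi**2 * big_r * r
        + 4.0 * math.pi * r**2
        - junction
        + n * curved_hole
        + tubule_area
    )
    return CurvatureBudget(
        total_area_nm2=flat + curved,
        flat_area_nm2=flat,
        curved_area_nm2=curved,
        adjusted_sheet_diameter_nm=2.0 * (big_r + r),
    )


def equivalent_tubule_length(
    n_holes: int,
    sheet_thickness_nm: float = 50.0,
    hole_inner_diameter_nm: float = 100.0,
    tubule_diameter_nm: float = 100.0,
) -> float:
    """Tubule length (nm) storing the same curved area as ``n_holes`` hole rims.

    ``L = n · A_rim / (π·d_tubule)`` — linear in the hole count and
    independent of the sheet disk size.
    """
    if n_holes < 0:
        raise ValueError("n_holes must be >= 0")
    curved, _ = hole_curved_area(sheet_thickness_nm, hole_inner_diameter_nm)
    return n_holes * curved / (math.pi * tubule_diameter_nm)


@dataclass(frozen=True)
class IsoclineFit:
    """Linear approximation of one constant-curved-fraction level set."""

    curved_fraction: float
    slope_holes_per_nm: float
    intercept_holes: float
    r_squared: float
    points: np.ndarray = field(repr=False)  # (n_holes, tubule_length_nm) samples


def isoclines(
    config: ERGeometryConfig,
    targets: tuple[float, ...] = (0.04, 0.06, 0.08, 0.10),
    n_holes_max: int = 60,
    tubule_length_max_nm: float = 6000.0,
    n_length_samples: int = 121,
) -> list[IsoclineFit]:
    """Extract and linearly fit level sets of the curved fraction.

    For each integer hole count the tubule length attaining each target
    curved fraction is located by monotone interpolation along a length
    sweep; the resulting (L, n) points are fitted by least squares.  The
    budget is affine in ``n`` and ``L`` up to the sheet-rim adjustment, so
    the fits are expected to be nearly exact (R² ≳ 0.999).
    """
    from dataclasses import replace

    lengths = np.linspace(0.0, tubule_length_max_nm, n_length_samples)
    fits: list[IsoclineFit] = []
    fractions = {}
    for n in range(n_holes_max + 1):
        vals = []
        for length in lengths:
            try:
                cfg = replace(config, n_holes=n, tubule_length_nm=float(length))
                vals.append(curvature_budget(cfg).curved_fraction)
            except ValueError:
                vals.append(np.nan)
        fractions[n] = np.asarray(vals)

    for target in targets:
        pts = []
        for n, vals in fractions.items():
            ok = np.isfinite(vals)
            v, ell = vals[ok], lengths[ok]
            if v.size < 2 or not (v.min() <= target <= v.max()):
                continue
            # curved fraction is monotone increasing in L
            pts.append((n, float(np.interp(target, v, ell))))
        if len(pts) < 2:
            continue
        arr = np.asarray(pts, dtype=float)
        n_arr, l_arr = arr[:, 0], arr[:, 1]
        slope, intercept = np.polyfit(l_arr, n_arr, 1)
        pred = slope * l_arr + intercept
        ss_res = float(np.sum((n_arr - pred) ** 2))
        ss_tot = float(np.sum((n_arr - n_arr.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        fits.append(
            IsoclineFit(
                curved_fraction=target,
                slope_holes_per_nm=float(slope),
                intercept_holes=float(intercept),
                r_squared=r2,
                points=arr,
            )
        )
    return fits
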