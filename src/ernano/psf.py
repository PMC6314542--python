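"""Lorentzian PSF kernels for STED image modeling.

STED point-spread functions are heavy-tailed and conventionally modeled as
Lorentzian.  Two discretized kernels are provided:

* a 1D unit-area Lorentzian, ``L(x) = (1/π)·γ/(x² + γ²)`` with half-width
  ``γ = Γ/2`` (FWHM Γ), used to blur 1D tubule cross-profiles;
* a radially symmetric 2D kernel ``K(r) = (γ/2π)·(r² + γ²)^(−3/2)`` whose
  *line-spread function* (integral along one axis) is exactly the 1D
  Lorentzian above.  A line-like structure imaged with the 2D kernel
  therefore has the same cross-profile as the 1D model — the property that
  keeps the image simulator and the profile-fit model consistent.

Lorentzian tails are heavy, so kernels are truncated at a finite radius
(default 20·Γ, leaving ≤ ~2.5% of the mass outside) and renormalized to
unit sum so convolution conserves flux.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lorentzian_1d_kernel", "lorentzian_2d_kernel"]

#: truncation radius in units of the FWHM
DEFAULT_TRUNCATION_FWHM = 20.0


def lorentzian_1d_kernel(fwhm_nm: float, spacing_nm: float, truncation_fwhm: float = DEFAULT_TRUNCATION_FWHM) -> np.ndarray:
    """Unit-sum 1D Lorentzian sampled every ``spacing_nm``, truncated and renormalized."""
    if fwhm_nm <= 0 or spacing_nm <= 0:
        raise ValueError("fwhm_nm and spacing_nm must be positive")
    gamma = fwhm_nm / 2.0
    half = int(np.ceil(truncation_fwhm * fwhm_nm / spacing_nm))
    x = np.arange(-half, half + 1) * spacing_nm
    kernel = gamma / (np.pi * (x**2 + gamma**2)) * spacing_nm
    return kernel / kernel.sum()


def lorentzian_2d_kernel(
    fwhm_nm: float,
    pixel_size_nm: float,
    truncation_fwhm: float = DEFAULT_TRUNCATION_FWHM,
    quadrature: int = 3,
) -> np.ndarray:
    """Unit-sum radially symmetric 2D Lorentzian kernel on a pixel grid.

    Each kernel pixel is evaluated by averaging ``quadrature²`` sub-samples
    so the sharp on-axis peak is integrated rather than point-sampled.
    """
    if fwhm_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("fwhm_nm and pixel_size_nm must be positive")
    gamma = fwhm_nm / 2.0
    half = int(np.ceil(truncation_fwhm * fwhm_nm / pixel_size_nm))
    idx = np.arange(-half, half + 1)
    sub = (np.arange(quadrature) + 0.5) / quadrature - 0.5
    # sub-sampled physical coordinates within each pixel
    coords = (idx[:, None] + sub[None, :]).ravel() * pixel_size_nm
    r2 = coords[:, None] ** 2 + coords[None, :] ** 2
    fine = gamma / (2.0 * np.pi) * (r2 + gamma**2) ** -1.5
    n = idx.size
    kernel = fine.reshape(n, quadrature, n, quadrature).mean(axis=(1, 3)) * pixel_size_nm**2
    mask = (idx[:, None] ** 2 + idx[None, :] ** 2) <= (truncation_fwhm * fwhm_nm / pixel_size_nm) ** 2
    kernel = np.where(mask, kernel, 0.0)
    return kernel / kernel.sum()
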