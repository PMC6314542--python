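"""Recover tubule diameters from simulated STED images by nested-grid fitting.

Simulates 50 surface-labeled (4.5-nm dye shell) tubules of true diameter
96 nm under a 50-nm Lorentzian PSF with a ~100-count peak, extracts
10-pixel-wide perpendicular line profiles, and fits each with the
annulus-projection model, scanning diameter and PSF FWHM jointly.
"""

import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from ernano.io import LineSpec, extract_profile
from ernano.simulate import SimulationConfig, alpha_for_peak, simulate_tubule_image
from ernano.tubules import FitGrid, TubuleGeometry, fit_profile, summarize_diameters

OUT = Path(__file__).resolve().parents[1] / "results"
TRUE_DIAMETER_NM = 96.0
PSF_FWHM_NM = 50.0
N_TUBULES = 50
BASE_SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    geom = TubuleGeometry("surface", annulus_thickness_nm=4.5)
    cfg = SimulationConfig(psf_fwhm_nm=PSF_FWHM_NM)
    cfg = replace(cfg, alpha=alpha_for_peak(100.0, TRUE_DIAMETER_NM, geom, cfg))
    grid = FitGrid()
    p = cfg.lateral_px_nm

    rows = []
    results = []
    for i, seed in enumerate(np.random.SeedSequence(BASE_SEED).spawn(N_TUBULES)):
        rng = np.random.default_rng(seed)
        noisy, truth = simulate_tubule_image(TRUE_DIAMETER_NM, geom, cfg, rng, n_px=64)
        row_nm = (truth.tubule_axis_row_px + 0.5) * p
        line = LineSpec((32 * p, row_nm - 378.0), (32 * p, row_nm + 378.0), width_px=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_profile(extract_profile(noisy, line), geom, grid)
        results.append(res)
        rows.append(
            {
                "tubule": i,
                "diameter_nm": res.diameter_nm,
                "psf_fwhm_nm": res.psf_fwhm_nm,
                "amplitude": res.amplitude,
                "background": res.background,
                "sse": res.sse,
                "fit_ok": res.fit_ok,
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "tubule_fits.csv", index=False)

    summary = summarize_diameters(results, bin_width_nm=10.0)
    print(
        f"simulated truth: d = {TRUE_DIAMETER_NM} nm, PSF FWHM = {PSF_FWHM_NM} nm, "
        f"n = {N_TUBULES} tubules"
    )
    print(
        f"recovered: {summary.mean_nm:.1f} +/- {summary.sd_nm:.1f} nm "
        f"(mean +/- SD; n = {summary.n}), range {summary.min_nm:.0f}-{summary.max_nm:.0f} nm"
    )
    print(
        f"pooled PSF FWHM: {summary.psf_fwhm_mean_nm:.1f} +/- {summary.psf_fwhm_sd_nm:.1f} nm"
    )


if __name__ == "__main__":
    main()
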