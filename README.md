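# ernano — nanoscale ER morphometry for STED microscopy

The peripheral endoplasmic reticulum (ER) is a continuum of flat membrane
sheets and highly curved tubules, and — as live-cell STED microscopy at
~50 nm resolution reveals — of **nanoholes**: sub-diffraction fenestrations
within otherwise uniform sheets, bounded by curved membrane rims. `ernano`
is a quantitative toolkit for this regime, aimed at microscopists analyzing
single-channel STED images (18.9 nm/px) of luminally or membrane-labeled
ER. It provides:

- **Nanohole segmentation** — the semiautomated chain: σ = 1 px Gaussian
  smoothing, local-minimum candidates (4-px minimum separation), an ER mask
  (15×15 median filter, 5%-of-max threshold), marker-controlled watershed,
  and a depth-based hole border: with hole depth
  *D* = mean(edge) − min(region), pixels below min + 0.4·*D* form the hole.
- **Hole morphometrics** — equivalent diameter *d* = 2√(A/π) and symmetry
  *s* = √(λ₂/λ₁) from the eigenvalues λ₁ ≥ λ₂ of the pixel-position
  covariance matrix (1 = circular), plus Kruskal–Wallis / Dunn group
  comparisons.
- **Tubule diameter fitting** — line profiles are fitted with the
  projection of a label-filled cylinder (lumen markers, P(x) = 2√(a² − x²))
  or a dye annulus (membrane markers, 4.5-nm shell for protein tags,
  17.5 nm with antibodies) convolved with a Lorentzian PSF, scanning
  diameter and PSF FWHM Γ in a nested grid that minimizes squared error.
- **A ground-truthed simulator** — 50-nm luminal slabs perforated by
  torus-edged holes (tube radius t/2), built at 1-nm axial sampling,
  projected, downsampled to 18.9-nm pixels, blurred with a 50-nm-FWHM
  Lorentzian PSF, and Poisson-sampled; plus tubule and sheet variants.
- **Hole tracking** — seeded frame-to-frame tracking with local-minimum
  center correction and persistence classification
  (persisted / appeared / disappeared / both).
- **A curvature budget** — an analytic fixed-area model of a disk sheet
  (outer rim = outer half-torus) with *n* nanoholes (inner half-torus rims)
  and a cylindrical tubule: each 100-nm hole in a 50-nm sheet stores
  2π²R·r − 4πr² ≈ 29,157 nm² of curved membrane, so ten holes hold the
  curved area of ≈ 0.93 µm of 100-nm tubule.

## Worked example

Recover tubule diameters from simulated images — 50 surface-labeled
tubules, true diameter 96 nm, PSF FWHM 50 nm, ~100-count peaks:

```sh
python analysis/03_fit_tubule_diameters.py
```

```
simulated truth: d = 96.0 nm, PSF FWHM = 50.0 nm, n = 50 tubules
recovered: 94.7 +/- 3.3 nm (mean +/- SD; n = 50), range 89-102 nm
pooled PSF FWHM: 56.8 +/- 4.0 nm
```

The mean recovered diameter lands within 1.5 nm of truth at this noise
level; the fitted Γ runs slightly wide because the fit absorbs the pixel
footprint into the PSF. The full analysis chain is scripted in order:

| script | what it does |
| --- | --- |
| `analysis/01_simulate_hole_fields.py` | generates the benchmark: 4 images × 25 holes × 7 inner diameters (30–200 nm) with ground truth |
| `analysis/02_segment_and_measure.py` | segments every field, measures hole diameter/symmetry, ranks recovered medians against truth |
| `analysis/03_fit_tubule_diameters.py` | simulates and fits the tubule cohort above |
| `analysis/04_curvature_budget.py` | curvature budgets, hole↔tubule equivalences, isocline fits for 30/50/100-nm sheets |
| `analysis/05_track_nanoholes.py` | tracks a scripted synthetic video and recovers its designed persistence partition |

Outputs (CSV tables, example TIFFs) land in `results/`. Segmenting the
benchmark sweep, for instance, yields median recovered diameters of
109 → 126 → 146 → 168 → 214 nm for inner diameters 75 → 100 → 125 → 150 →
200 nm: the 40%-depth border sits on the curved rim, so recovered values
fall between the inner diameter and the rim's outer extent and rank
strictly with truth.

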