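# hilicraman

Chemometric analysis of two-dimensional HILIC-Raman data: matrices of Raman
intensity over wavenumber × elution time recorded on-line behind a
hydrophilic-interaction (HILIC) column. The package resolves such matrices
into chemically meaningful component spectra and elution curves, quantifies
analytes by peak-area calibration with detection limits, and ships a
synthetic-data generator that emulates the five-sugar separation study
(fructose, glucose, sucrose, maltose, trehalose in 65% aqueous acetonitrile)
so the entire chain is testable with known ground truth — no instrument data
required.

It is written for analytical chemists and chemometricians working with
hyphenated LC–spectroscopy data who want a small, transparent, fully tested
reference implementation of SVD target-transformation factor analysis.

## The method

A run is an *m* × *n* matrix **M** (wavenumber channels × time points),
modeled as bilinear: each chemical component contributes an outer product of
its spectrum and its elution profile. The analysis is:

1. **Economy SVD** of the observed channels:
   **M** = **U°WV°**ᵀ, with **U°** spectral factors, **V°** temporal
   factors, **W** the singular values. The number of significant components
   *m*₁ is read from the singular-value scree (or forced).
2. **Target rotation.** A regular *m*₁ × *m*₁ matrix **K** rotates the
   truncated factors onto model spectra:

   **M** ≈ **U°**ₘ₁**W**ₘ₁**V°**ₘ₁ᵀ = (**U°**ₘ₁**K**)(**K**⁻¹**W**ₘ₁**V°**ₘ₁ᵀ) = **U′V′**ᵀ

   Because **U°**ₘ₁ has orthonormal columns, the least-squares column for
   target *t*ⱼ is closed-form, *k*ⱼ = **U°**ₘ₁ᵀ*t*ⱼ; remaining columns span
   the orthogonal complement within the truncated subspace. The product
   **U′V′**ᵀ equals the truncated reconstruction exactly for any regular
   **K** — the rotation reinterprets the factors, it never refits the data.
3. **Quantification.** Columns of **V′** are elution curves. Peaks are
   characterized by Gaussian fits (with constant offset), areas by
   trapezoidal window integrals, and amounts by area ratio to a
   single-standard run of known injected amount. Linear calibration over a
   concentration series gives LOD = 3·*s*ₑ/|slope| and LOQ = 10·*s*ₑ/|slope|
   (*s*ₑ = residual standard error), so LOQ/LOD = 10/3 by construction.
   An analyte is reported as detected only when its model spectrum is
   actually reproduced by the data subspace (target-testing residual ≤ 0.5)
   and its area clears the LOD-equivalent amount.

Masked wavenumber channels — the computational image of the physical
solvent-line rejection mask — are excluded from the SVD and all fits, never
imputed. The solvent background is removed beforehand with a per-column
least-squares scale, because its intensity fluctuates with the flow.

## Worked example

Resolving a noisy synthetic five-sugar mixture
(`python examples/03_target_rotation.py`):

```
rank m1 = 9, cond(K) = 99.8, rotation conservation error = 2.61e-16
sugar fit residual  elution (min)  true (min)
Fru         0.1018          36.66       36.66
Glu         0.1082          39.56       39.57
Suc         0.1127          42.95       42.95
Mal         0.0996          46.66       46.66
Tre         0.1071          47.97       47.97
```

The small fit residuals say each rotated spectrum reproduces its model
spectrum; the recovered elution centers match the ground truth to the
hundredth of a minute, in the order Fru < Glu < Suc < Mal < Tre spanning
~11.3 min. The end-to-end driver
(`python examples/05_honey_composition.py`) quantifies a honey-like sample
against single-sugar standards:

```
sugar center/min      wt%  residual  detected
Fru        36.66    39.88     0.004  True
Glu        39.57    26.48     0.006  True
Suc        42.54     1.49     0.324  True
Mal        45.37     0.00     0.693  False
Tre        47.77     0.00     0.767  False
Fru + Glu = 66.4 wt%
```

Fru, Glu and Suc are quantified (wt% of the sample mass); Mal and Tre —
truly absent from the simulated sample — fail the spectral identification
test and are flagged not detected.

Each script in `examples/` is a short narrative of one capability:
simulation, solvent subtraction, target rotation, calibration with LOD/LOQ,
and the full composition analysis. A thin CLI wraps the same stages:
`hilicraman simulate|preprocess|decompose|quantify|run`.

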