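# Methods

## The bilinear model

A 2D HILIC-Raman measurement is treated as an *m* × *n* matrix **M** of
counts, rows indexed by Raman shift (cm⁻¹) and columns by elution time
(min). Every chemical or instrumental component *k* is assumed to
contribute a separable term, spectrum × temporal profile:

    M = Σ_k  a_k b_kᵀ  +  E

with **E** detector noise. This is the standard assumption behind factor
analysis of hyphenated data; it holds as long as spectra do not change shape
with time (no concentration-dependent band shifts, no co-eluting
interactions). Everything downstream — SVD, rank selection, target rotation,
peak quantification — lives on top of this model.

## Synthetic data generator

The generator (`simulate`, `presets`) produces matrices with exactly this
structure plus controlled violations (noise, fluctuations), with the
generating truth attached so recovery can be scored. It emulates the
five-sugar HILIC separation study:

| ingredient | model | default |
|---|---|---|
| wavenumber axis | uniform grid | 200–1800 cm⁻¹, 1024 channels |
| time axis | uniform grid | 30–55 min, one spectrum / 4 s (n = 375) |
| sugar spectra | sums of Gaussian bands, unit peak | 4–5 bands each in the 480–1460 cm⁻¹ fingerprint region (glucose marker at 1130 cm⁻¹) |
| ACN (solvent) | 3 sharp bands (380, 920, 1375 cm⁻¹) | amplitude 50 counts |
| water | 2 broad bands (600, 1640 cm⁻¹) | amplitude 15 counts |
| elution peaks | exponentially modified Gaussian, area-normalized to the Gaussian limit | centers 36.4 / 39.3 / 42.7 / 46.4 / 47.7 min, σ 0.45–0.6 min, tail 0.3 min |
| response | temporal amplitude per concentration | 0.02 counts/mM |
| solvent fluctuation | zero-mean AR(1) multiplier, φ = 0.9 | σ = 1% of solvent amplitude |
| baseline | constant spectrum, level minus elution dip | level 0.5; dip = 0.2 × summed analyte signal (kept proportional so the synthesis stays bilinear) |
| band-shift artifact | analytic first derivative of the ACN band sum | AR(1) amplitude, σ 0.2 |
| drift (single runs) | linear ramp spectrum × slow temporal ramp | amplitude 0.1 |
| detector noise | additive homoscedastic Gaussian | σ = 1% of the strongest analyte signal unless set |
| mask | channels inside closed intervals unobserved (NaN) | band cores (368–392, 908–932, 1363–1387 cm⁻¹); wings stay observed |

A single-standard run therefore has six independent components (analyte,
ACN, water, baseline, band shift, drift) and a five-sugar mixture nine (no
drift) — the component counts the analysis should find.

What the generator does **not** emulate: wavenumber miscalibration between
runs, cosmic-ray spikes, shot (signal-proportional) noise by default,
retention-time drift between sample and standard runs, spectral shape
changes with concentration, and co-elution chemistry. Passing tests
therefore demonstrate the correctness of the algebra and the behavior of
the estimators under the stated noise model, not robustness to every
instrument pathology.

## Preprocessing

* **Block averaging** collapses consecutive spectra (raw cadence → analysis
  cadence); a trailing partial block is dropped with a warning.
* **Cropping** keeps a closed time window. A degenerate single-column window
  is widened to two columns (the containers require ≥ 2 time points).
* **Solvent subtraction** removes a reference solvent spectrum with a
  per-column scale, fitted by least squares on designated scale channels
  (defaults: the wings of the strong 920 cm⁻¹ ACN band, outside the mask).
  Per-column scaling is needed because the solvent intensity fluctuates with
  the flow; the operation is idempotent and never touches masked channels.
  Subtraction artifacts near mask edges can be removed explicitly by
  widening the mask a configurable ± cm⁻¹, never by automatic outlier
  deletion.

## Decomposition

* **SVD** runs on the observed channels only; masked rows are excluded, not
  zero-filled (zero-filling manufactures spurious components at mask edges).
* **Rank selection** maximizes the log-gap of consecutive singular values
  over a search range; a user-forced rank always wins. Under realistic noise
  the dominant gap sits after the solvent component, so the pipeline's
  automatic policy feeds `n_targets + 2` vectors at minimum — deliberately
  over-including, the way practitioners feed extra vectors to catch minor
  and background structure. Extra components land in free columns and do
  not perturb the targeted ones.
* **Target rotation.** Targets are peak-normalized (max |value| = 1) before
  fitting, and restricted to observed channels. The fitted columns of **K**
  are closed-form projections (`k_j = U°ᵀ t_j`); the free columns are an
  orthonormal basis of the complement within the truncated subspace, ordered
  by variance explained (metric diag(**W**²)). The paper-gap here — how the
  rotation is computed — is resolved in favor of the closed form because the
  iterative least squares it replaces has the identical optimum and the
  closed form is deterministic; an iterative hook for constrained variants
  (e.g. non-negative elution curves) is a possible extension, off by
  default.
* **Sign conventions.** Targeted components keep a positive inner product
  with their target (automatic for projections); each free component's
  largest-magnitude temporal element is made positive.
* **Degenerate inputs.** Collinear targets are rejected at library
  construction (Gram condition > 1e8); a singular rotation (cond(**K**) >
  1e12) raises with the most collinear pair named.
* **Normalization.** `unit-temporal` scales each elution curve to max
  |value| = 1 with the inverse scale on its spectrum, leaving the product
  unchanged to 1e-12; spectral magnitudes then read as component
  contributions.
* Background model: the constant baseline spectrum is always a *target*,
  not a free component — its elution-coincident dip otherwise leaks into
  analyte curves. Single-standard decompositions additionally target a
  linear-ramp background (slow drift); without it the drift's
  concentration-independent offset biases calibration slopes by ~2.5%.

## Quantification and detection

* **Peak fits**: Gaussian with constant offset by nonlinear least squares;
  area = height·σ·√(2π); non-convergence falls back to the window integral
  and is flagged. Fitting a Gaussian to a tailed (EMG) peak biases the
  center late — recovery comparisons therefore apply the same estimator to
  recovered and true curves so the bias cancels.
* **Areas**: trapezoidal integrals over closed windows; default windows
  35.3–38.0 (Fru), 38.0–40.7 (Glu), 40.7–43.3 (Suc), 44.7–47.3 (Mal),
  46.0–49.0 (Tre) min. Mal/Tre windows overlap; this is tolerated because
  the *rotated* curves are separate.
* **Calibration**: ordinary least squares of area vs concentration (mM);
  LOD = 3·se/|slope|, LOQ = 10·se/|slope| — multipliers 3 and 10, fixed.
  Molar limits convert to mass units by the molecular weight
  (mM × g/mol = µg/mL). Shipped weights: Fru/Glu 180.16, Suc/Mal/Tre 342.3.
* **wt%**: injected amount = standard amount × (sample area / standard
  area); wt% relates the analyte mass to the sample mass in the injected
  aliquot. Window integrals are used for sample and standard symmetrically.
* **Detection** is two-gated. (1) *Identification*: the analyte's model
  spectrum must be reproduced by the truncated subspace — relative
  target-fit residual ≤ 0.5, i.e. more than half the spectrum's norm
  explained. This is the classical target-testing criterion, and it is what
  actually separates a genuinely absent analyte from noise: an absent
  target's rotated curve carries noise amplified through near-collinear
  dual vectors, which can exceed a calibration-derived LOD by an order of
  magnitude. (2) *Quantity*: the area must exceed the LOD-equivalent
  amount. Failing either flags the analyte not-detected (never silently
  zero). Under the default conditions the residual separates cleanly:
  ~0.005 for major components, ~0.3 for sucrose at 1.3 mM, ~0.7 for absent
  sugars.

## Pipeline

`run_pipeline` chains simulate → preprocess → decompose → quantify from a
flat YAML config: it synthesizes replicate sample matrices (default 3,
averaged — the usual triplicate protocol), one single-standard run per
analyte, and a 5-point calibration series per analyte; decomposes all of
them identically; and writes every stage output plus a machine-readable
summary carrying the config hash. Identical config + seed reproduce every
output byte for byte. Matrix files are one dialect everywhere:
tab-delimited text, time axis in the first row, wavenumber axis in the
first column, `NA` for unobserved cells; minutes and cm⁻¹ throughout.

## Problem sizes

Tests and the acceptance script run entirely on synthetic data at the
default geometry (1024 × 375). Recovery statistics use 20 seeded noisy
mixtures; calibration statistics use 3 replicate 5-point series; the
composition analysis averages replicate syntheses (3 in the bundled demos,
9 in the acceptance script, which tightens the stochastic wt% estimates).
The full suite completes in well under a minute.

## Known limitations

* Free (untargeted) components are only identified up to rotation within
  their subspace; they absorb structure, they are not interpretable shapes.
* Absent-target curves are noise amplified by the dual basis; their areas
  are meaningless except for the detection test.
* The EMG tail constant is not estimated — peaks are quantified by window
  area, not by tailed-peak deconvolution, so strongly overlapping elution
  of spectrally similar analytes degrades gracefully but is not modeled.
* Uncertainty propagation stops at regression standard errors; replicate
  scatter is averaged, not propagated into the reported wt%.
* No wavenumber alignment between runs: sample and standards are assumed on
  one calibrated axis.
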