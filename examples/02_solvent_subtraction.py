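"""Per-column solvent subtraction on a fluctuating solvent background.

The 65% ACN running solvent dominates the raw matrix and its intensity
fluctuates with the flow, so a single fixed subtraction under- or
over-corrects.  Here each column gets its own least-squares scale estimated
on solvent-band wing channels before the reference spectrum is removed.
"""

import numpy as np

from hilicraman import presets
from hilicraman.preprocess import SolventReference, subtract_solvent
from hilicraman.simulate import ar1_series, make_elution_profile, synthesize_matrix

waxis = presets.default_wavenumber_axis()
taxis = presets.default_time_axis()
spectra = presets.model_spectra(waxis)

rng = np.random.default_rng(1)
solvent_series = 50.0 * (1.0 + ar1_series(len(taxis), 0.01, 0.9, rng))
glu_series = make_elution_profile(
    presets.ELUTION_DEFAULTS["Glu"], taxis
) * (25.0 * presets.RESPONSE_PER_MM)

chrom, _ = synthesize_matrix(
    [(spectra["ACN"], solvent_series), (spectra["Glu"], glu_series)],
    taxis, noise_sigma=0.0,
)
ref = SolventReference(spectra["ACN"], presets.default_scale_channels())
corrected, scales = subtract_solvent(chrom, ref)

resid = np.abs(corrected.intensities - np.outer(spectra["Glu"].profile, glu_series))
print(f"solvent amplitude: mean {scales.mean():.2f}, sd {scales.std():.3f} counts")
print(f"scale series tracks the simulated fluctuation: "
      f"corr = {np.corrcoef(scales, solvent_series)[0, 1]:.6f}")
print(f"max residual after subtraction vs pure analyte matrix: {resid.max():.2e}")
print("-> the solvent is removed column by column; the glucose contribution")
print("   survives untouched because its bands avoid the scale channels.")
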