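"""Resolve a noisy five-sugar matrix into spectra and elution curves.

Truncated SVD factors are rotated by a regular matrix K so the spectral
factors match the model spectra of the five sugars, the solvents, the ACN
band-shift artifact and a constant baseline.  The paired temporal factors are
then the elution curves, read off for peak position and area.
"""

import numpy as np

from hilicraman import presets
from hilicraman.decompose import ComponentLibrary, svd_factor, target_rotation
from hilicraman.quantify import fit_gaussian_peak

chrom, truth = presets.sugar_mixture_run(
    {s: 25.0 for s in presets.SUGARS}, seed=3, masked=True
)
spectra = presets.model_spectra(chrom.waxis)
lib = ComponentLibrary(
    [spectra[s] for s in presets.SUGARS]
    + [spectra["ACN"], spectra["H2O"], spectra["ACN-shift"], spectra["baseline"]]
)
D = target_rotation(svd_factor(chrom), 9, lib)

print(f"rank m1 = {D.m1}, cond(K) = {D.cond_K:.1f}, "
      f"rotation conservation error = {D.reconstruction_error():.2e}")
print(f"{'sugar':5s} {'fit residual':>12s} {'elution (min)':>14s} {'true (min)':>11s}")
for name in presets.SUGARS:
    j = D.target_names.index(name)
    pk = fit_gaussian_peak(D.taxis.values, D.curve(name),
                           presets.INTEGRATION_WINDOWS[name], name)
    tr = fit_gaussian_peak(D.taxis.values, truth.true_series(name),
                           presets.INTEGRATION_WINDOWS[name], name)
    print(f"{name:5s} {D.fit_residual[j]:12.4f} {pk.center:14.2f} {tr.center:11.2f}")
print("-> residuals near zero mean each rotated spectrum reproduces its model;")
print("   the sugars elute in order Fru < Glu < Suc < Mal < Tre over ~11.3 min.")
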