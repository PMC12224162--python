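"""Synthesize a five-sugar HILIC-Raman matrix and inspect its structure.

Builds the default masked 2D matrix (wavenumber x elution time) for an
equimolar 25 mM mixture of fructose, glucose, sucrose, maltose and trehalose
in 65% acetonitrile, then counts its significant components from the
singular-value spectrum.
"""

import numpy as np

from hilicraman import presets
from hilicraman.decompose import select_rank, svd_factor

chrom, truth = presets.sugar_mixture_run(
    {s: 25.0 for s in presets.SUGARS}, seed=0, noise_sigma=0.0, masked=True
)
print(f"matrix: {chrom.n_channels} wavenumber channels x {chrom.n_times} spectra")
print(f"masked channels (solvent line rejection): {(~chrom.observed).sum()}")

F = svd_factor(chrom)
print("largest 12 singular values:")
print(" ", np.array2string(F.s[:12], precision=3, suppress_small=True))
m1 = select_rank(F.s)
print(f"significant components (scree log-gap): {m1}")
print("-> 5 sugars + ACN + water + ACN band shift + baseline = 9 bilinear terms;")
print("   with detector noise off, exactly 9 singular values stand above zero.")
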