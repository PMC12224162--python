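"""Raw-data conditioning: block averaging, time cropping, solvent subtraction.

The running solvent (65% aqueous ACN) dominates the raw Raman matrix and its
intensity fluctuates over time with the flow, so the solvent reference is
rescaled per column by least squares on designated solvent-only wavenumber
windows before subtraction.  Masked (unobserved) channels are carried through
untouched — never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ComponentSpectrum, MaskSpec, SpectroChromatogram, TimeAxis

__all__ = ["SolventReference", "block_average", "crop_window", "subtract_solvent", "widen_mask"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolventReference:
    """Solvent spectrum plus the wavenumber windows used for per-column scaling."""

    profile: ComponentSpectrum
    scale_channels: tuple[tuple[float, float], ...]

    def __init__(self, profile: ComponentSpectrum, scale_channels) -> None:
        object.__setattr__(self, "profile", profile)
        object.__setattr__(
            self,
            "scale_channels",
            tuple((float(lo), float(hi)) for lo, hi in scale_channels),
        )

    def channel_indices(self, chrom: SpectroChromatogram) -> np.ndarray:
        """Indices of observed channels inside the scale windows."""
        w = chrom.waxis.values
        sel = np.zeros(len(w), dtype=bool)
        for lo, hi in self.scale_channels:
            sel |= (w >= lo) & (w <= hi)
        sel &= chrom.observed
        return np.flatnonzero(sel)


def block_average(chrom: SpectroChromatogram, block: int) -> SpectroChromatogram:
    """Average consecutive groups of ``block`` columns (spectra).

    Emulates on-line accumulation: many short exposures averaged into each
    stored spectrum.  A trailing partial block is dropped with a warning.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    n = chrom.n_times
    if block > n:
        raise ValueError(f"block size {block} exceeds column count {n}")
    if block == 1:
        return chrom.copy()
    n_full = n // block
    if n_full * block != n:
        log.warning("dropping %d trailing columns not filling a block", n - n_full * block)
    M = chrom.intensities[:, : n_full * block].reshape(chrom.n_channels, n_full, block)
    t = chrom.taxis.values[: n_full * block].reshape(n_full, block)
    return SpectroChromatogram(
        M.mean(axis=2), chrom.waxis, TimeAxis(t.mean(axis=1)), chrom.observed.copy()
    )


def crop_window(chrom: SpectroChromatogram, t0: float, t1: float) -> SpectroChromatogram:
    """Keep columns with elution time in the closed interval [t0, t1]."""
    sel = (chrom.taxis.values >= t0) & (chrom.taxis.values <= t1)
    if not sel.any():
        raise ValueError(f"no columns in time window [{t0}, {t1}] min")
    if sel.sum() == 1:
        # TimeAxis requires two points; duplicate-column windows are degenerate
        idx = int(np.flatnonzero(sel)[0])
        lo = max(idx - 1, 0) if idx == chrom.n_times - 1 else idx
        sel = np.zeros_like(sel)
        sel[lo : lo + 2] = True
        warnings.warn("single-column window widened to two columns", stacklevel=2)
    return SpectroChromatogram(
        chrom.intensities[:, sel],
        chrom.waxis,
        TimeAxis(chrom.taxis.values[sel]),
        chrom.observed.copy(),
    )


def subtract_solvent(
    chrom: SpectroChromatogram, ref: SolventReference
) -> tuple[SpectroChromatogram, np.ndarray]:
    """Subtract a per-column-scaled solvent spectrum.

    For each column j the scale s_j minimizes ``||M[:, j] - s_j * ref||`` over
    the observed scale channels; the scaled reference is then subtracted from
    all observed channels of that column.  Returns the corrected matrix and
    the scale series s_j.
    """
    idx = ref.channel_indices(chrom)
    if idx.size < 3:
        raise ValueError("scale windows contain fewer than 3 observed channels")
    r = ref.profile.profile[idx]
    denom = float(r @ r)
    if denom <= 1e-12 * idx.size * max(1.0, float(np.max(np.abs(ref.profile.profile))) ** 2):
        raise ValueError("solvent reference is ~0 on the scale channels; fit degenerate")
    scales = (r @ chrom.intensities[idx, :]) / denom
    out = chrom.intensities.copy()
    obs = chrom.observed
    out[obs] = out[obs] - np.outer(ref.profile.profile[obs], scales)
    log.info(
        "solvent subtraction: %d scale channels, mean scale %.4g",
        idx.size,
        float(np.mean(scales)),
    )
    return SpectroChromatogram(out, chrom.waxis, chrom.taxis, obs.copy()), scales


def widen_mask(mask: MaskSpec, margin_cm1: float) -> MaskSpec:
    """Widen every masked interval by ±margin, to drop subtraction artifacts
    at mask edges explicitly rather than by outlier heuristics."""
    if margin_cm1 < 0:
        raise ValueError("margin must be >= 0")
    return MaskSpec([(lo - margin_cm1, hi + margin_cm1) for lo, hi in mask.intervals])
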