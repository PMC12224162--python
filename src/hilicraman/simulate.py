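"""Synthetic 2D HILIC-Raman data with known ground truth.

The generator builds a spectro-chromatogram as a sum of rank-one terms,
outer(spectrum, elution curve), plus additive detector noise — the same
bilinear model the SVD/target-rotation analysis assumes.  Every simulated
ingredient mirrors a feature of the real measurement: sugar Raman band
patterns, a sharp acetonitrile (ACN) solvent spectrum and a broad water
spectrum, zero-mean flow-instability fluctuation of the solvent intensity, a
baseline dip coincident with analyte elution, a derivative-shaped component
from small shifts of the ACN bands, exponentially modified Gaussian (EMG)
elution peaks with tailing, and a spectral mask of unobserved channels.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ComponentSpectrum, MaskSpec, SpectroChromatogram, TimeAxis, WavenumberAxis

__all__ = [
    "ElutionProfileSpec",
    "GroundTruth",
    "make_component_spectra",
    "make_elution_profile",
    "synthesize_matrix",
    "apply_mask",
    "residence_time",
    "ar1_series",
]


@dataclass(frozen=True)
class ElutionProfileSpec:
    """Elution peak parameters: Gaussian center/width plus exponential tail.

    ``tail`` is the time constant (min) of the exponential convolution; 0 gives
    a symmetric Gaussian.  ``amplitude`` scales with concentration.  The EMG is
    area-normalized against its Gaussian limit, so the integrated peak area is
    amplitude * width * sqrt(2*pi) regardless of tailing.
    """

    center: float
    width: float
    tail: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("elution width (sigma) must be > 0")
        if self.tail < 0:
            raise ValueError("tail time constant must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _band_sum(
    band_table, axis: WavenumberAxis, shape: str, derivative: bool
) -> np.ndarray:
    x = axis.values
    out = np.zeros_like(x)
    for center, width, height in band_table:
        if width <= 0:
            raise ValueError(f"band width must be positive, got {width}")
        if not axis.contains(center):
            raise ValueError(
                f"band center {center} cm^-1 outside axis "
                f"[{x[0]}, {x[-1]}] cm^-1"
            )
        u = (x - center) / width
        if shape == "gaussian":
            if derivative:
                out += height * (-u / width) * np.exp(-0.5 * u * u)
            else:
                out += height * np.exp(-0.5 * u * u)
        elif shape == "lorentzian":
            if derivative:
                out += height * (-2 * u / width) / (1 + u * u) ** 2
            else:
                out += height / (1 + u * u)
        else:
            raise ValueError(f"unknown band shape {shape!r}")
    return out


def make_component_spectra(
    band_table,
    axis: WavenumberAxis,
    kind: str = "analyte",
    name: str = "component",
    shape: str = "gaussian",
) -> ComponentSpectrum:
    """Build a model spectrum as a sum of Gaussian (or Lorentzian) bands.

    Parameters
    ----------
    band_table : sequence of (center cm^-1, width cm^-1, height)
        One entry per Raman band; width is the Gaussian sigma (or Lorentzian
        half-width).
    kind : str
        Spectrum class; ``"derivative-artifact"`` returns the analytic first
        derivative of the band sum, modelling a small solvent band shift.
    """
    if len(band_table) == 0:
        raise ValueError("band table is empty")
    derivative = kind == "derivative-artifact"
    profile = _band_sum(band_table, axis, shape, derivative)
    return ComponentSpectrum(name=name, axis=axis, profile=profile, kind=kind)


def make_elution_profile(spec: ElutionProfileSpec, axis: TimeAxis) -> np.ndarray:
    """Evaluate an elution peak on a time axis.

    Pure Gaussian when ``tail == 0`` (maximum exactly ``amplitude`` at
    ``center``); exponentially modified Gaussian otherwise, scaled so the
    integrated area matches the Gaussian of the same amplitude and width.
    """
    t = axis.values
    if not axis.contains(spec.center):
        warnings.warn(
            f"elution center {spec.center} min outside time axis "
            f"[{t[0]}, {t[-1]}] min; peak will be clipped",
            stacklevel=2,
        )
    if spec.amplitude == 0:
        return np.zeros_like(t)
    if spec.tail == 0:
        u = (t - spec.center) / spec.width
        return spec.amplitude * np.exp(-0.5 * u * u)
    from scipy.stats import exponnorm

    k = spec.tail / spec.width
    pdf = exponnorm.pdf(t, k, loc=spec.center, scale=spec.width)
    return spec.amplitude * spec.width * np.sqrt(2 * np.pi) * pdf


def ar1_series(
    n: int, sigma: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean AR(1) series with stationary standard deviation ``sigma``.

    Models the flow-instability fluctuation of the solvent Raman intensity.
    """
    if not 0 <= phi < 1:
        raise ValueError("AR(1) coefficient must be in [0, 1)")
    eps = rng.normal(scale=sigma * np.sqrt(1 - phi * phi), size=n)
    out = np.empty(n)
    out[0] = rng.normal(scale=sigma)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


@dataclass
class GroundTruth:
    """Everything needed to score a recovery against the simulation.

    ``components`` pairs each model spectrum with the exact temporal series
    used in the synthesis; ``elution`` and ``concentrations`` describe the
    analytes.  Identical seed + parameters regenerate identical matrices.
    """

    components: list[tuple[ComponentSpectrum, np.ndarray]]
    elution: dict[str, ElutionProfileSpec] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int | None = None

    def true_series(self, name: str) -> np.ndarray:
        for spectrum, series in self.components:
            if spectrum.name == name:
                return series
        raise KeyError(f"no component named {name!r}")

    def spectrum(self, name: str) -> ComponentSpectrum:
        for spectrum, _ in self.components:
            if spectrum.name == name:
                return spectrum
        raise KeyError(f"no component named {name!r}")


def synthesize_matrix(
    components: list[tuple[ComponentSpectrum, np.ndarray]],
    taxis: TimeAxis,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[SpectroChromatogram, GroundTruth]:
    """Sum rank-one spectrum x elution terms and add Gaussian detector noise.

    All spectra must share one wavenumber axis and all temporal series the
    length of ``taxis``.  Deterministic under a fixed seed.
    """
    if not components:
        raise ValueError("no components to synthesize")
    axis = components[0][0].axis
    n = len(taxis)
    M = np.zeros((len(axis), n))
    for spectrum, series in components:
        if spectrum.axis is not axis and not np.array_equal(
            spectrum.axis.values, axis.values
        ):
            raise ValueError(f"spectrum {spectrum.name!r} is on a different axis")
        series = np.asarray(series, dtype=float)
        if series.shape != (n,):
            raise ValueError(
                f"temporal series for {spectrum.name!r} has length "
                f"{series.size}, expected {n}"
            )
        M += np.outer(spectrum.profile, series)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        M = M + rng.normal(scale=noise_sigma, size=M.shape)
    chrom = SpectroChromatogram(M, axis, taxis)
    truth = GroundTruth(
        components=[(s, np.asarray(v, dtype=float)) for s, v in components],
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return chrom, truth


def apply_mask(chrom: SpectroChromatogram, mask: MaskSpec) -> SpectroChromatogram:
    """Flag channels inside the mask intervals as unobserved (NaN sentinel).

    Observed values are untouched; a mask covering every channel is an error
    since nothing would remain observable.
    """
    flags = mask.channel_flags(chrom.waxis)
    observed = chrom.observed & ~flags
    if not observed.any():
        raise ValueError("mask covers the entire wavenumber axis")
    out = chrom.intensities.copy()
    out[~observed] = np.nan
    return SpectroChromatogram(out, chrom.waxis, chrom.taxis, observed)


def residence_time(volume_mm3: float, flow_rate_ml_min: float) -> float:
    """Time (ms) for the eluate to traverse a flow volume (mm^3) at a flow
    rate (mL/min).  1 mL/min = 1000 mm^3 / 60000 ms."""
    if volume_mm3 <= 0 or flow_rate_ml_min <= 0:
        raise ValueError("volume and flow rate must be strictly positive")
    return volume_mm3 * 60.0 / flow_rate_ml_min
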