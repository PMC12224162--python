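"""Default study conditions for the five-sugar HILIC-Raman experiments.

These constants pin down the synthetic studies the test-bench reproduces:
isocratic HILIC of fructose (Fru), glucose (Glu), sucrose (Suc), maltose (Mal)
and trehalose (Tre) in 65% aqueous acetonitrile, Raman detection over
200-1800 cm^-1, the 30-55 min analysis window at one averaged spectrum per
4 s, and a spatial mask that blocks the strong ACN lines.

Band tables are stylised but chemically motivated: sugars share C-O/C-C
stretch bands in the 1000-1150 cm^-1 fingerprint region (glucose's marker band
sits at 1130 cm^-1) plus distinct CH/COH deformation bands, ACN contributes a
few sharp lines, and water a broad bending/libration background.
"""

from __future__ import annotations

import numpy as np

from .core import ComponentSpectrum, MaskSpec, TimeAxis, WavenumberAxis
from .simulate import (
    ElutionProfileSpec,
    GroundTruth,
    apply_mask,
    ar1_series,
    make_component_spectra,
    make_elution_profile,
    synthesize_matrix,
)

__all__ = [
    "SUGARS",
    "MOLECULAR_WEIGHTS",
    "SUGAR_BANDS",
    "ELUTION_DEFAULTS",
    "INTEGRATION_WINDOWS",
    "RESPONSE_PER_MM",
    "default_wavenumber_axis",
    "default_time_axis",
    "default_mask",
    "default_scale_channels",
    "model_spectra",
    "sugar_mixture_run",
    "single_sugar_run",
    "honey_like_concentrations",
]

SUGARS = ("Fru", "Glu", "Suc", "Mal", "Tre")

#: g/mol; mono-saccharides 180.16, di-saccharides 342.3
MOLECULAR_WEIGHTS = {
    "Fru": 180.16,
    "Glu": 180.16,
    "Suc": 342.3,
    "Mal": 342.3,
    "Tre": 342.3,
}

# (center cm^-1, sigma cm^-1, relative height)
SUGAR_BANDS = {
    "Fru": [(630, 12, 0.7), (825, 10, 1.0), (1070, 12, 0.6), (1265, 12, 0.5), (1460, 14, 0.4)],
    "Glu": [(520, 12, 0.5), (850, 10, 0.6), (1065, 12, 0.8), (1130, 10, 1.0), (1365, 14, 0.45)],
    "Suc": [(540, 12, 0.6), (835, 10, 1.0), (1045, 12, 0.5), (1130, 10, 0.7), (1460, 12, 0.35)],
    "Mal": [(480, 12, 0.5), (850, 10, 0.8), (1080, 12, 0.7), (1120, 10, 1.0), (1355, 12, 0.4)],
    "Tre": [(530, 12, 0.55), (845, 10, 0.9), (1110, 12, 1.0), (1380, 12, 0.3), (1460, 12, 0.4)],
}

ACN_BANDS = [(380, 6, 0.3), (920, 6, 1.0), (1375, 8, 0.5)]
WATER_BANDS = [(600, 150, 0.6), (1640, 50, 1.0)]

#: elution center (min), Gaussian sigma (min), exponential tail constant (min)
ELUTION_DEFAULTS = {
    "Fru": ElutionProfileSpec(center=36.4, width=0.45, tail=0.3),
    "Glu": ElutionProfileSpec(center=39.3, width=0.50, tail=0.3),
    "Suc": ElutionProfileSpec(center=42.7, width=0.55, tail=0.3),
    "Mal": ElutionProfileSpec(center=46.4, width=0.60, tail=0.3),
    "Tre": ElutionProfileSpec(center=47.7, width=0.60, tail=0.3),
}

#: integration windows (min) used for peak-area quantification; Mal and Tre
#: overlap, which is tolerated because the rotated elution curves are separate.
INTEGRATION_WINDOWS = {
    "Fru": (35.3, 38.0),
    "Glu": (38.0, 40.7),
    "Suc": (40.7, 43.3),
    "Mal": (44.7, 47.3),
    "Tre": (46.0, 49.0),
}

#: temporal peak amplitude (counts) per mM of injected sugar
RESPONSE_PER_MM = 0.02

# solvent / background scales relative to RESPONSE_PER_MM (counts)
ACN_AMPLITUDE = 50.0
WATER_AMPLITUDE = 15.0
BASELINE_LEVEL = 0.5
#: the baseline dips by this fraction of the summed analyte signal during
#: elution (refractive-index / solvent-fraction effect); proportional to the
#: analyte amplitudes so the synthesis stays bilinear in concentration
BASELINE_DIP_FACTOR = 0.2
SHIFT_SIGMA = 0.2  # derivative-artifact amplitude sd
FLUCTUATION_SIGMA = 0.01  # solvent fluctuation, fraction of solvent amplitude
AR1_PHI = 0.9


def default_wavenumber_axis(n_channels: int = 1024) -> WavenumberAxis:
    """200-1800 cm^-1 grid."""
    return WavenumberAxis(np.linspace(200.0, 1800.0, n_channels))


def default_time_axis(t0: float = 30.0, t1: float = 55.0, step_s: float = 4.0) -> TimeAxis:
    """Analysis window, one averaged spectrum per ``step_s`` seconds."""
    step = step_s / 60.0
    n = int(round((t1 - t0) / step))
    return TimeAxis(t0 + step * np.arange(n))


def default_mask() -> MaskSpec:
    """Intervals blocking the cores of the ACN lines (band wings stay observed)."""
    return MaskSpec([(368, 392), (908, 932), (1363, 1387)])


def default_scale_channels() -> list[tuple[float, float]]:
    """Wavenumber windows on the wings of the strong 920 cm^-1 ACN band, used
    to estimate the per-column solvent scale outside the mask."""
    return [(890.0, 906.0), (934.0, 950.0)]


def model_spectra(axis: WavenumberAxis, shape: str = "gaussian") -> dict[str, ComponentSpectrum]:
    """Peak-normalized model spectra: five sugars, ACN, water, constant
    baseline, ACN band-shift derivative, and a sloping drift shape."""
    out: dict[str, ComponentSpectrum] = {}
    for name, bands in SUGAR_BANDS.items():
        out[name] = make_component_spectra(bands, axis, "analyte", name, shape).peak_normalized()
    out["ACN"] = make_component_spectra(ACN_BANDS, axis, "solvent", "ACN", shape).peak_normalized()
    out["H2O"] = make_component_spectra(WATER_BANDS, axis, "solvent", "H2O", shape).peak_normalized()
    out["baseline"] = ComponentSpectrum(
        "baseline", axis, np.ones(len(axis)), kind="constant"
    )
    out["ACN-shift"] = make_component_spectra(
        ACN_BANDS, axis, "derivative-artifact", "ACN-shift", shape
    ).peak_normalized()
    x = axis.values
    ramp = 0.2 + 0.8 * (x - x[0]) / (x[-1] - x[0])
    out["drift"] = ComponentSpectrum("drift", axis, ramp, kind="baseline")
    return out


def _study_run(
    concentrations: dict[str, float],
    *,
    seed: int,
    noise_sigma: float | None,
    include_drift: bool,
    masked: bool,
    waxis: WavenumberAxis | None,
    taxis: TimeAxis | None,
):
    for name in concentrations:
        if name not in SUGARS:
            raise KeyError(f"unknown sugar {name!r}; expected one of {SUGARS}")
    waxis = waxis or default_wavenumber_axis()
    taxis = taxis or default_time_axis()
    spectra = model_spectra(waxis)
    rng = np.random.default_rng(seed)
    n = len(taxis)

    analytes = {
        name: ElutionProfileSpec(
            center=ELUTION_DEFAULTS[name].center,
            width=ELUTION_DEFAULTS[name].width,
            tail=ELUTION_DEFAULTS[name].tail,
            amplitude=RESPONSE_PER_MM * conc,
        )
        for name, conc in concentrations.items()
        if conc > 0
    }
    analyte_series = {
        name: make_elution_profile(spec, taxis) for name, spec in analytes.items()
    }
    summed = (
        np.sum(list(analyte_series.values()), axis=0)
        if analyte_series
        else np.zeros(n)
    )

    components: list[tuple[ComponentSpectrum, np.ndarray]] = []
    for name, series in analyte_series.items():
        components.append((spectra[name], series))
    acn_fluct = ar1_series(n, FLUCTUATION_SIGMA, AR1_PHI, rng)
    h2o_fluct = ar1_series(n, FLUCTUATION_SIGMA, AR1_PHI, rng)
    components.append((spectra["ACN"], ACN_AMPLITUDE * (1.0 + acn_fluct)))
    components.append((spectra["H2O"], WATER_AMPLITUDE * (1.0 + h2o_fluct)))
    dip = BASELINE_LEVEL - BASELINE_DIP_FACTOR * summed
    components.append((spectra["baseline"], dip))
    components.append((spectra["ACN-shift"], ar1_series(n, SHIFT_SIGMA, AR1_PHI, rng)))
    if include_drift:
        ramp = 0.1 * (taxis.values - taxis.values[0]) / (taxis.values[-1] - taxis.values[0])
        components.append((spectra["drift"], ramp + 0.02))

    if noise_sigma is None:
        analyte_max = max((s.max() for s in analyte_series.values()), default=0.0)
        noise_sigma = 0.01 * analyte_max
    chrom, truth = synthesize_matrix(
        components, taxis, noise_sigma=noise_sigma, seed=int(rng.integers(2**31))
    )
    truth.elution = analytes
    truth.concentrations = dict(concentrations)
    truth.seed = seed
    if masked:
        chrom = apply_mask(chrom, default_mask())
    return chrom, truth


def sugar_mixture_run(
    concentrations: dict[str, float],
    seed: int = 0,
    noise_sigma: float | None = None,
    masked: bool = True,
    waxis: WavenumberAxis | None = None,
    taxis: TimeAxis | None = None,
):
    """Synthesize a mixture run: analytes + ACN + H2O + baseline (with elution
    dip) + ACN band-shift artifact.  With all five sugars present this is a
    nine-component bilinear model.  ``noise_sigma=None`` defaults to 1% of the
    strongest analyte signal; pass 0 for a noiseless matrix."""
    return _study_run(
        concentrations,
        seed=seed,
        noise_sigma=noise_sigma,
        include_drift=False,
        masked=masked,
        waxis=waxis,
        taxis=taxis,
    )


def single_sugar_run(
    name: str,
    concentration_mm: float,
    seed: int = 0,
    noise_sigma: float | None = None,
    masked: bool = True,
    waxis: WavenumberAxis | None = None,
    taxis: TimeAxis | None = None,
):
    """Synthesize a single-standard run.  Includes a slow baseline-drift
    component in addition to the mixture ingredients, giving the six-component
    structure seen in single-sugar experiments."""
    return _study_run(
        {name: concentration_mm},
        seed=seed,
        noise_sigma=noise_sigma,
        include_drift=True,
        masked=masked,
        waxis=waxis,
        taxis=taxis,
    )


def honey_like_concentrations(
    wt_percent: dict[str, float] | None = None,
    mass_g: float = 1.0,
    volume_ml: float = 20.0,
) -> dict[str, float]:
    """Injected-solution concentrations (mM) for a honey-like sample.

    Defaults to the composition Fru 39.9, Glu 26.5, Suc 0.9 wt% with Mal and
    Tre absent, dissolved 1 g in 20 mL.
    """
    if wt_percent is None:
        wt_percent = {"Fru": 39.9, "Glu": 26.5, "Suc": 0.9, "Mal": 0.0, "Tre": 0.0}
    out = {}
    for name, wt in wt_percent.items():
        grams = mass_g * wt / 100.0
        out[name] = grams / MOLECULAR_WEIGHTS[name] / (volume_ml / 1000.0) * 1000.0
    return out
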