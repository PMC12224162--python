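"""Peak quantification, calibration and sample composition.

Resolved elution curves are reduced to numbers in three steps: a Gaussian fit
(with constant offset) characterizes each peak, trapezoidal window integrals
give areas, and ordinary least-squares calibration over a concentration
series yields the limit of detection LOD = 3*se/|slope| and limit of
quantification LOQ = 10*se/|slope|, where se is the residual standard error
of the regression — so LOQ/LOD is 10/3 by construction.  Weight-percent
composition of a complex sample follows from the ratio of its peak area to
that of a single standard of known injected amount.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "ElutionPeak",
    "CalibrationResult",
    "SampleQuantification",
    "fit_gaussian_peak",
    "integrate_window",
    "linear_calibration",
    "convert_concentration",
    "quantify_wt_percent",
]

log = logging.getLogger(__name__)


@dataclass
class ElutionPeak:
    """Gaussian parameters and integrated area of one resolved elution peak."""

    analyte: str
    center: float
    sigma: float
    height: float
    area: float
    window: tuple[float, float]
    offset: float = 0.0
    converged: bool = True
    detected: bool = True


@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration of response against concentration (mM) with detection
    limits in molar (mM) and, when a molecular weight is given, mass
    (ug/mL) units."""

    slope: float
    intercept: float
    se_resid: float
    r2: float
    lod_molar: float
    loq_molar: float
    mw: float | None = None
    lod_mass: float | None = None
    loq_mass: float | None = None


@dataclass(frozen=True)
class SampleQuantification:
    """Amount of one analyte in a diluted sample, as injected mmol and wt%."""

    analyte: str
    injected_amount_mmol: float
    wt_percent: float
    detected: bool
    dilution: tuple[float, float, float]


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 < t0:
        raise ValueError(f"window ({t0}, {t1}) has end before start")
    sel = (times >= t0) & (times <= t1)
    if not sel.any():
        raise ValueError(f"window [{t0}, {t1}] min contains no data points")
    return sel


def fit_gaussian_peak(
    times: np.ndarray,
    curve: np.ndarray,
    window: tuple[float, float],
    analyte: str = "",
) -> ElutionPeak:
    """Fit height * exp(-(t-c)^2 / 2s^2) + offset inside the window.

    The constant offset absorbs residual baseline.  Non-convergence is
    flagged and the area falls back to the window integral; a windowful of
    zeros is reported as not detected.  Area of a converged fit is the
    closed form height * sigma * sqrt(2*pi).
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    sel = _window_slice(times, window)
    if sel.sum() < 5:
        raise ValueError("window contains fewer than 5 points")
    t, y = times[sel], curve[sel]

    if np.max(np.abs(y)) == 0:
        return ElutionPeak(analyte, float(np.mean(window)), np.nan, 0.0, 0.0,
                           window, converged=False, detected=False)

    def gauss(x, c, s, h, b):
        return h * np.exp(-0.5 * ((x - c) / s) ** 2) + b

    i0 = int(np.argmax(y))
    span = window[1] - window[0]
    p0 = (t[i0], span / 6.0, float(y[i0] - y.min()), float(y.min()))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                gauss, t, y, p0=p0,
                bounds=([t[0] - span, 1e-6, -np.inf, -np.inf],
                        [t[-1] + span, 5 * span, np.inf, np.inf]),
                maxfev=10000,
            )
        c, s, h, b = (float(v) for v in popt)
        area = h * s * np.sqrt(2 * np.pi)
        return ElutionPeak(analyte, c, s, h, area, window, offset=b,
                           converged=True, detected=h > 0)
    except RuntimeError:
        area = float(np.trapezoid(y - y.min(), t))
        log.info("Gaussian fit did not converge for %r; window-sum fallback", analyte)
        return ElutionPeak(analyte, float(t[i0]), np.nan, float(y[i0]), area,
                           window, converged=False, detected=True)


def integrate_window(
    times: np.ndarray, curve: np.ndarray, window: tuple[float, float]
) -> float:
    """Trapezoidal integral of the curve over points inside the closed window."""
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    sel = _window_slice(times, window)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than 2 points; integral undefined")
    return float(np.trapezoid(curve[sel], times[sel]))


def linear_calibration(
    points,
    origin_forced: bool = False,
    mw: float | None = None,
) -> CalibrationResult:
    """Ordinary least squares of response against concentration (mM).

    Detection limits follow the residual-standard-error convention:
    LOD = 3*se/|slope|, LOQ = 10*se/|slope| (both mM); mass-unit limits are
    obtained by multiplying by the molecular weight (mM * g/mol = ug/mL).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, response) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("concentrations have zero variance; regression undefined")
    n = x.size
    if origin_forced:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        dof = n - 1
    else:
        xm, ym = x.mean(), y.mean()
        slope = float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))
        intercept = float(ym - slope * xm)
        dof = n - 2
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se_resid = np.sqrt(ss_res / dof) if dof > 0 else 0.0
    if slope == 0:
        raise ValueError("calibration slope is zero; LOD undefined")
    lod = 3.0 * se_resid / abs(slope)
    loq = 10.0 * se_resid / abs(slope)
    return CalibrationResult(
        slope=slope, intercept=intercept, se_resid=float(se_resid), r2=float(r2),
        lod_molar=float(lod), loq_molar=float(loq), mw=mw,
        lod_mass=float(lod * mw) if mw else None,
        loq_mass=float(loq * mw) if mw else None,
    )


def convert_concentration(value_ug_ml: float, mw: float) -> float:
    """ug/mL -> mM given the molecular weight (g/mol)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return value_ug_ml / mw


def quantify_wt_percent(
    sample_peak: ElutionPeak,
    standard_peak: ElutionPeak,
    standard: tuple[float, float],
    dilution: tuple[float, float, float],
    mw: float,
    lod_mm: float | None = None,
) -> SampleQuantification:
    """Weight percent of an analyte in a sample via peak-area ratio.

    ``standard`` is (concentration mM, injected volume mL) of a single-analyte
    standard run; ``dilution`` is (sample mass g, dissolution volume mL,
    injected volume mL).  Injected amount scales the standard's amount by the
    area ratio; wt% relates the analyte mass to the sample mass contained in
    the injected aliquot.  Areas at or below the LOD-equivalent area (from
    ``lod_mm``, a concentration in the injected solution) are flagged not
    detected.
    """
    if sample_peak.analyte != standard_peak.analyte:
        raise ValueError(
            f"analyte mismatch: sample {sample_peak.analyte!r} vs "
            f"standard {standard_peak.analyte!r}"
        )
    if standard_peak.area <= 0:
        raise ValueError("standard peak area must be positive")
    std_conc_mm, std_inj_ml = standard
    mass_g, volume_ml, inj_ml = dilution
    if min(std_conc_mm, std_inj_ml, mass_g, volume_ml, inj_ml) <= 0:
        raise ValueError("standard and dilution parameters must be positive")

    std_mmol = std_conc_mm * std_inj_ml / 1000.0
    injected_mmol = std_mmol * sample_peak.area / standard_peak.area
    analyte_mg = injected_mmol * mw
    aliquot_mg = mass_g * 1000.0 * inj_ml / volume_ml
    wt = analyte_mg / aliquot_mg * 100.0

    detected = sample_peak.detected and sample_peak.area > 0
    if detected and lod_mm is not None:
        lod_mmol = lod_mm * inj_ml / 1000.0
        if injected_mmol <= lod_mmol:
            detected = False
    if not detected:
        injected_mmol = 0.0
        wt = 0.0
    wt = float(np.clip(wt, 0.0, 100.0))
    return SampleQuantification(
        analyte=sample_peak.analyte,
        injected_amount_mmol=float(injected_mmol),
        wt_percent=wt,
        detected=detected,
        dilution=dilution,
    )
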