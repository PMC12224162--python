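"""Core containers for 2D spectro-chromatographic data.

A HILIC-Raman run is an ``m x n`` matrix of Raman intensities: rows are
wavenumber channels (cm^-1), columns are elution times (min).  A spatial
line-rejection mask may remove whole wavenumber channels from observation;
masked channels are tracked with a per-row boolean flag and carry NaN in the
intensity matrix.  The mask is spectral: a channel is either observed at every
time point or at none.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WavenumberAxis",
    "TimeAxis",
    "MaskSpec",
    "ComponentSpectrum",
    "SpectroChromatogram",
]

SPECTRUM_KINDS = ("analyte", "solvent", "derivative-artifact", "constant", "baseline")


def _as_1d_float(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniformly spaced, strictly increasing grid of Raman shifts (cm^-1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_1d_float(self.values, "wavenumber axis")
        if arr.size < 2:
            raise ValueError("wavenumber axis needs at least 2 channels")
        d = np.diff(arr)
        if np.any(d <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if np.max(np.abs(d - d[0])) > 1e-9 * abs(d[0]):
            raise ValueError("wavenumber axis must be uniformly spaced")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def contains(self, wavenumber: float) -> bool:
        return bool(self.values[0] <= wavenumber <= self.values[-1])


@dataclass(frozen=True)
class TimeAxis:
    """Strictly increasing elution-time grid (min)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_1d_float(self.values, "time axis")
        if arr.size < 2:
            raise ValueError("time axis needs at least 2 points")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("time axis must be strictly increasing")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def nearest_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.values - t)))

    def contains(self, t: float) -> bool:
        return bool(self.values[0] <= t <= self.values[-1])


@dataclass(frozen=True)
class MaskSpec:
    """Closed wavenumber intervals excluded from observation.

    Emulates the physical barcode mask that blocks solvent Raman lines before
    detection.  Overlapping or touching intervals are merged on construction.
    """

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Sequence[Sequence[float]] = ()) -> None:
        cleaned: list[tuple[float, float]] = []
        for iv in intervals:
            lo, hi = float(iv[0]), float(iv[1])
            if hi < lo:
                raise ValueError(f"mask interval ({lo}, {hi}) has hi < lo")
            cleaned.append((lo, hi))
        cleaned.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in cleaned:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        object.__setattr__(self, "intervals", tuple(merged))

    def channel_flags(self, axis: WavenumberAxis) -> np.ndarray:
        """Boolean array, True where a channel falls inside a masked interval."""
        flags = np.zeros(len(axis), dtype=bool)
        for lo, hi in self.intervals:
            flags |= (axis.values >= lo) & (axis.values <= hi)
        return flags


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named model spectrum on a wavenumber axis.

    ``kind`` classifies the physical origin: an analyte band pattern, a solvent
    spectrum, the derivative-shaped artifact produced by a solvent band shift,
    a constant background, or a slowly varying baseline shape.  Analyte and
    solvent profiles must be non-negative; a derivative artifact must integrate
    to ~0 over the full axis (it redistributes rather than adds intensity).
    """

    name: str
    axis: WavenumberAxis
    profile: np.ndarray
    kind: str = "analyte"

    def __post_init__(self) -> None:
        prof = _as_1d_float(self.profile, "profile")
        if prof.size != len(self.axis):
            raise ValueError("profile length does not match axis")
        if not np.all(np.isfinite(prof)):
            raise ValueError(f"spectrum {self.name!r} has non-finite values")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind in ("analyte", "solvent") and np.any(prof < 0):
            raise ValueError(f"{self.kind} spectrum {self.name!r} must be non-negative")
        if self.kind == "derivative-artifact":
            integral = abs(np.trapezoid(prof, self.axis.values))
            l1 = np.trapezoid(np.abs(prof), self.axis.values)
            if l1 > 0 and integral > 1e-6 * l1:
                raise ValueError(
                    f"derivative artifact {self.name!r} does not integrate to ~0"
                )
        object.__setattr__(self, "profile", prof)

    def peak_normalized(self) -> "ComponentSpectrum":
        m = np.max(np.abs(self.profile))
        if m == 0:
            return self
        return dataclasses.replace(self, profile=self.profile / m)

    def restricted(self, rows: np.ndarray) -> np.ndarray:
        """Profile values on a subset of channels (for masked fitting)."""
        return self.profile[rows]


@dataclass
class SpectroChromatogram:
    """The ``m x n`` data matrix with its axes and channel-observation flags.

    Unobserved (masked) channels are NaN in ``intensities`` and False in
    ``observed``; observed entries must be finite.
    """

    intensities: np.ndarray
    waxis: WavenumberAxis
    taxis: TimeAxis
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.waxis), len(self.taxis)):
            raise ValueError(
                f"matrix shape {self.intensities.shape} does not match axes "
                f"({len(self.waxis)}, {len(self.taxis)})"
            )
        if self.observed is None:
            self.observed = np.all(np.isfinite(self.intensities), axis=1)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (len(self.waxis),):
                raise ValueError("observed flags must have one entry per channel")
        obs_rows = self.intensities[self.observed]
        if not np.all(np.isfinite(obs_rows)):
            raise ValueError("observed channels contain non-finite intensities")
        unobs = self.intensities[~self.observed]
        if unobs.size and np.any(np.isfinite(unobs)):
            raise ValueError("unobserved channels must be NaN at every time point")

    @property
    def n_channels(self) -> int:
        return len(self.waxis)

    @property
    def n_times(self) -> int:
        return len(self.taxis)

    @property
    def observed_rows(self) -> np.ndarray:
        return np.flatnonzero(self.observed)

    def observed_submatrix(self) -> np.ndarray:
        return self.intensities[self.observed]

    def copy(self) -> "SpectroChromatogram":
        return SpectroChromatogram(
            self.intensities.copy(), self.waxis, self.taxis, self.observed.copy()
        )
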