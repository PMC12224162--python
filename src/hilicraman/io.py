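"""Flat-text I/O for matrices, spectra and run artifacts.

One matrix dialect everywhere: tab-delimited, first row the elution-time axis
(min), first column the wavenumber axis (cm^-1), body in counts, unobserved
cells written as ``NA``.  Time in minutes and wavenumber in cm^-1 throughout;
no unit autodetection.  Round trips are exact for finite values and NA
sentinels (Python float repr).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ComponentSpectrum, SpectroChromatogram, TimeAxis, WavenumberAxis

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_spectrum",
    "read_spectrum",
    "write_key_values",
    "read_key_values",
]

_INDEX_LABEL = "wavenumber_cm-1"


def write_matrix(chrom: SpectroChromatogram, path) -> None:
    df = pd.DataFrame(
        chrom.intensities,
        index=[repr(float(v)) for v in chrom.waxis.values],
        columns=[repr(float(v)) for v in chrom.taxis.values],
    )
    df.to_csv(path, sep="\t", na_rep="NA", index_label=_INDEX_LABEL)


def read_matrix(path) -> SpectroChromatogram:
    """Read the tab-delimited matrix dialect; NA rows become unobserved
    channels.  Ragged rows, non-monotonic axes, or partially-NA rows (the
    mask is spectral, never temporal) raise with the offending line."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix file: {exc}") from exc
    try:
        w = df.index.to_numpy(dtype=float)
        t = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric axis header: {exc}") from exc
    bad = np.flatnonzero(np.diff(w) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: wavenumber axis not strictly increasing at data line "
            f"{int(bad[0]) + 2}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time axis header not strictly increasing")
    M = df.to_numpy(dtype=float)
    finite = np.isfinite(M)
    partial = np.flatnonzero(finite.any(axis=1) & ~finite.all(axis=1))
    if partial.size:
        raise ValueError(
            f"{path}: row at data line {int(partial[0]) + 2} mixes NA and "
            f"values; masked channels must be NA at every time point"
        )
    return SpectroChromatogram(M, WavenumberAxis(w), TimeAxis(t), finite.all(axis=1))


def write_spectrum(spectrum: ComponentSpectrum, path) -> None:
    """Two-column TSV: wavenumber, intensity; kind/name in a # header."""
    with open(path, "w") as fh:
        fh.write(f"# name={spectrum.name}\tkind={spectrum.kind}\n")
        fh.write(f"{_INDEX_LABEL}\tintensity\n")
        for w, v in zip(spectrum.axis.values, spectrum.profile):
            fh.write(f"{float(w)!r}\t{float(v)!r}\n")


def read_spectrum(path) -> ComponentSpectrum:
    name, kind = Path(path).stem, "analyte"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(
            part.split("=", 1) for part in first[1:].strip().split("\t") if "=" in part
        )
        name = meta.get("name", name)
        kind = meta.get("kind", kind)
        skip = 1
    else:
        skip = 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    return ComponentSpectrum(
        name=name,
        axis=WavenumberAxis(df.iloc[:, 0].to_numpy(dtype=float)),
        profile=df.iloc[:, 1].to_numpy(dtype=float),
        kind=kind,
    )


def _plain(value):
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.ndarray):
        return [_plain(v) for v in value]
    return value


def write_key_values(data: dict, path) -> None:
    """Flat YAML-style key-value text (sorted keys, deterministic output)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=True, default_flow_style=False)


def read_key_values(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
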