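"""SVD factorization and target rotation of spectro-chromatograms.

The analysis model is bilinear: ``M = U° W V°^T`` (economy SVD; U° spectral
factors, V° temporal factors, W singular values).  After truncating to the
``m1`` significant components, a regular ``m1 x m1`` matrix K rotates the
abstract factors onto chemically meaningful ones::

    M ≈ U°_m1 W_m1 V°_m1^T = (U°_m1 K)(K^-1 W_m1 V°_m1^T) = U' V'^T

Columns of K for targeted components solve the least-squares match of
``U°_m1 k_j`` to each model spectrum; because U°_m1 has orthonormal columns
the optimum is closed form, ``k_j = U°_m1^T t_j``.  Untargeted ("free")
columns span the orthogonal complement within the truncated subspace, ordered
by variance explained.  The product U'V'^T always equals the truncated
reconstruction exactly, whatever K — the rotation reinterprets, never refits.

Masked (unobserved) wavenumber channels are excluded from both the SVD and
the target fit; zero-filling them would manufacture spurious components.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ComponentSpectrum, SpectroChromatogram, TimeAxis, WavenumberAxis

__all__ = [
    "SVDFactors",
    "ComponentLibrary",
    "DecompositionResult",
    "svd_factor",
    "select_rank",
    "target_rotation",
    "normalize_components",
]

log = logging.getLogger(__name__)


@dataclass
class SVDFactors:
    """Economy SVD of the observed part of a spectro-chromatogram.

    ``U`` has one row per *observed* wavenumber channel; ``observed_rows``
    maps those rows back onto the full axis.
    """

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray
    observed_rows: np.ndarray
    waxis: WavenumberAxis
    taxis: TimeAxis

    @property
    def rank(self) -> int:
        return self.s.size

    def reconstruct(self, m1: int | None = None) -> np.ndarray:
        """Truncated reconstruction on the observed channels."""
        m1 = self.rank if m1 is None else m1
        return (self.U[:, :m1] * self.s[:m1]) @ self.V[:, :m1].T


@dataclass(frozen=True)
class ComponentLibrary:
    """Ordered model spectra to rotate onto, plus free-component count.

    ``n_free`` is the number of unconstrained components appended after the
    targets (baseline/residual structure); None lets the rotation fill the
    truncated rank.  Targets must be mutually linearly independent.
    """

    targets: tuple[ComponentSpectrum, ...]
    n_free: int | None = None

    def __init__(self, targets, n_free: int | None = None) -> None:
        targets = tuple(targets)
        if not targets:
            raise ValueError("component library needs at least one target")
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate target names in component library")
        T = np.column_stack([t.peak_normalized().profile for t in targets])
        gram = T.T @ T
        if np.linalg.cond(gram) > 1e8:
            raise ValueError("target spectra are nearly collinear (Gram condition > 1e8)")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "n_free", n_free)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets)


@dataclass
class DecompositionResult:
    """Rotated factors: spectral components U' and elution curves V'.

    ``Uprime`` is on the full wavenumber axis with NaN at masked channels;
    ``Vprime`` columns are the elution curves of the components, ordered as
    the library targets followed by free components.  ``fit_residual`` is the
    relative L2 mismatch between each rotated spectrum and its target.
    """

    m1: int
    K: np.ndarray
    cond_K: float
    Uprime: np.ndarray
    Vprime: np.ndarray
    component_names: tuple[str, ...]
    target_names: tuple[str, ...]
    fit_residual: np.ndarray
    waxis: WavenumberAxis
    taxis: TimeAxis
    observed_rows: np.ndarray
    factors: SVDFactors = field(repr=False)

    def curve(self, name: str) -> np.ndarray:
        return self.Vprime[:, self.component_names.index(name)]

    def spectrum(self, name: str) -> np.ndarray:
        return self.Uprime[:, self.component_names.index(name)]

    def reconstruction_error(self) -> float:
        """Relative Frobenius mismatch of U'V'^T against the truncated SVD."""
        ref = self.factors.reconstruct(self.m1)
        rec = self.Uprime[self.observed_rows] @ self.Vprime.T
        return float(np.linalg.norm(rec - ref) / np.linalg.norm(ref))


def svd_factor(chrom: SpectroChromatogram) -> SVDFactors:
    """Economy SVD of the observed channels of the matrix.

    The singular-value list has length ``min(m_observed, n)``.  Non-finite
    observed entries are an error.
    """
    rows = chrom.observed_rows
    M = chrom.intensities[rows]
    if not np.all(np.isfinite(M)):
        raise ValueError("observed part of the matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return SVDFactors(U, s, Vt.T, rows, chrom.waxis, chrom.taxis)


def select_rank(
    s: np.ndarray,
    method: str = "gap",
    k: int | None = None,
    search_range: tuple[int, int] = (1, 30),
) -> int:
    """Choose the number of significant components from the singular values.

    A user-supplied ``k`` always wins (analyses sometimes deliberately
    over-include components to hunt for minor constituents).  Otherwise the
    rank maximizing the log-gap ``log(s_i / s_{i+1})`` over the search range
    is returned — the scree-plot elbow read automatically.
    """
    s = np.asarray(s, dtype=float)
    if k is not None:
        if k < 1 or k > s.size:
            raise ValueError(f"forced rank {k} outside 1..{s.size}")
        return int(k)
    if method != "gap":
        raise ValueError(f"unknown rank-selection method {method!r}")
    lo, hi = search_range
    hi = min(hi, s.size - 1)
    if hi < lo:
        raise ValueError("search range empty for this singular-value list")
    floor = s[0] * 1e-15 if s[0] > 0 else 1e-300
    sf = np.maximum(s, floor)
    gaps = np.log(sf[lo - 1 : hi] / sf[lo : hi + 1])
    m1 = int(lo + np.argmax(gaps))
    log.info("rank selection: gap method chose m1=%d", m1)
    return m1


def _free_columns(K_fit: np.ndarray, s_m1: np.ndarray, n_free: int) -> np.ndarray:
    """Orthonormal basis of the complement of the fitted columns within the
    truncated subspace, ordered by variance explained (diag(s^2) metric)."""
    m1 = s_m1.size
    if n_free == 0:
        return np.zeros((m1, 0))
    if K_fit.shape[1] == 0:
        Q = np.eye(m1)
    else:
        # null space of K_fit^T
        _, _, Vt = np.linalg.svd(K_fit.T, full_matrices=True)
        Q = Vt[K_fit.shape[1]:].T
    G = Q.T @ (s_m1[:, None] ** 2 * Q)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:n_free]
    return Q @ evecs[:, order]


def target_rotation(
    F: SVDFactors, m1: int, lib: ComponentLibrary
) -> DecompositionResult:
    """Rotate the truncated SVD factors onto the library's model spectra.

    Targets are peak-normalized and restricted to the observed channels before
    fitting.  V' is computed as ``V°_m1 W_m1 K^-T`` so that U'V'^T equals the
    truncated reconstruction exactly.
    """
    p = len(lib.targets)
    if m1 < p:
        raise ValueError(f"rank m1={m1} smaller than number of targets {p}")
    if m1 > F.rank:
        raise ValueError(f"rank m1={m1} exceeds available components {F.rank}")
    n_free = m1 - p
    if lib.n_free is not None and lib.n_free != n_free:
        warnings.warn(
            f"library requests {lib.n_free} free components; rank m1={m1} "
            f"with {p} targets leaves {n_free}",
            stacklevel=2,
        )

    U1 = F.U[:, :m1]
    s1 = F.s[:m1]
    T = np.column_stack(
        [t.peak_normalized().profile[F.observed_rows] for t in lib.targets]
    )
    if not np.all(np.isfinite(T)):
        raise ValueError("targets contain non-finite values on observed channels")
    # closed-form least squares: U1 has orthonormal columns
    K_fit = U1.T @ T
    fitted = U1 @ K_fit
    norms = np.linalg.norm(T, axis=0)
    residual = np.linalg.norm(fitted - T, axis=0) / np.where(norms > 0, norms, 1.0)

    K = np.column_stack([K_fit, _free_columns(K_fit, s1, n_free)])
    cond = float(np.linalg.cond(K))
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(T.T) if p > 1 else np.ones((1, 1))
        worst = np.unravel_index(
            np.argmax(np.abs(corr - np.eye(p))), corr.shape
        )
        raise ValueError(
            f"rotation matrix K is singular (cond={cond:.3g}); most collinear "
            f"targets: {lib.names[worst[0]]!r} and {lib.names[worst[1]]!r}"
        )
    Kinv = np.linalg.inv(K)
    Uprime_obs = U1 @ K
    Vprime = F.V[:, :m1] @ (s1[:, None] * Kinv.T)

    # sign conventions: targeted columns already have positive overlap with
    # their targets (k_j = U^T t_j); free columns get their largest-magnitude
    # temporal element made positive.
    for j in range(p, m1):
        i = int(np.argmax(np.abs(Vprime[:, j])))
        if Vprime[i, j] < 0:
            Vprime[:, j] *= -1
            Uprime_obs[:, j] *= -1
            K[:, j] *= -1

    m_full = len(F.waxis)
    Uprime = np.full((m_full, m1), np.nan)
    Uprime[F.observed_rows] = Uprime_obs
    names = list(lib.names) + [f"free{i + 1}" for i in range(n_free)]
    log.info(
        "target rotation: m1=%d, %d targets, cond(K)=%.3g, max residual %.3g",
        m1, p, cond, float(residual.max()),
    )
    return DecompositionResult(
        m1=m1,
        K=K,
        cond_K=cond,
        Uprime=Uprime,
        Vprime=Vprime,
        component_names=tuple(names),
        target_names=lib.names,
        fit_residual=residual,
        waxis=F.waxis,
        taxis=F.taxis,
        observed_rows=F.observed_rows,
        factors=F,
    )


def normalize_components(
    D: DecompositionResult, mode: str = "unit-temporal"
) -> DecompositionResult:
    """Rescale paired factor columns without changing their product.

    ``unit-temporal`` sets each elution curve's max |value| to 1 and applies
    the inverse scale to the paired spectrum, so spectral magnitudes read as
    component contributions.  All-zero components are left unscaled.
    """
    if mode != "unit-temporal":
        raise ValueError(f"unknown normalization mode {mode!r}")
    U = D.Uprime.copy()
    V = D.Vprime.copy()
    for j in range(D.m1):
        scale = np.max(np.abs(V[:, j]))
        if scale == 0:
            warnings.warn(
                f"component {D.component_names[j]!r} is all-zero; left unscaled",
                stacklevel=2,
            )
            continue
        V[:, j] /= scale
        U[:, j] *= scale
    return dataclasses.replace(D, Uprime=U, Vprime=V)
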