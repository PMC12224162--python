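import dataclasses

import numpy as np
import pytest

from hilicraman import presets
from hilicraman.core import ComponentSpectrum, SpectroChromatogram, TimeAxis, WavenumberAxis
from hilicraman.decompose import (
    ComponentLibrary,
    normalize_components,
    select_rank,
    svd_factor,
    target_rotation,
)

from conftest import full_library


class TestSvdFactor:
    def test_agrees_with_eigendecomposition_oracle(self, rng):
        """On a small matrix, singular values must match the square roots of
        the eigenvalues of M^T M, and the reconstruction must be exact."""
        M = rng.normal(size=(20, 10))
        waxis = WavenumberAxis(np.linspace(200, 1800, 20))
        taxis = TimeAxis(np.linspace(30, 55, 10))
        F = svd_factor(SpectroChromatogram(M, waxis, taxis))
        evals = np.linalg.eigvalsh(M.T @ M)[::-1]
        np.testing.assert_allclose(F.s, np.sqrt(np.clip(evals, 0, None)), atol=1e-8)
        np.testing.assert_allclose(F.reconstruct(), M, atol=1e-10)
        # orthonormality of both factor sets
        np.testing.assert_allclose(F.U.T @ F.U, np.eye(10), atol=1e-8)
        np.testing.assert_allclose(F.V.T @ F.V, np.eye(10), atol=1e-8)

    def test_rank_one_input(self, rng):
        M = np.outer(rng.random(30), rng.random(12))
        waxis = WavenumberAxis(np.linspace(200, 1800, 30))
        taxis = TimeAxis(np.linspace(30, 55, 12))
        F = svd_factor(SpectroChromatogram(M, waxis, taxis))
        assert F.s[1] < 1e-10 * F.s[0]

    def test_masked_channels_excluded(self, noiseless_mixture):
        chrom, _ = noiseless_mixture
        F = svd_factor(chrom)
        assert F.U.shape[0] == chrom.observed.sum()
        assert F.s.size == min(int(chrom.observed.sum()), chrom.n_times)

    def test_nonfinite_observed_entry_rejected(self):
        waxis = WavenumberAxis(np.linspace(200, 1800, 8))
        taxis = TimeAxis(np.linspace(30, 55, 4))
        M = np.zeros((8, 4))
        M[1, 1] = np.inf
        with pytest.raises(ValueError):
            svd_factor(SpectroChromatogram(M, waxis, taxis))


class TestSelectRank:
    def test_dominant_gap(self):
        assert select_rank(np.array([100.0, 50.0, 1e-8, 1e-9])) == 2

    def test_noiseless_single_sugar_run_has_six_components(self, noiseless_fru):
        chrom, _ = noiseless_fru
        assert select_rank(svd_factor(chrom).s) == 6

    def test_forced_rank_overrides_gap(self):
        s = np.array([100.0, 50, 20, 10, 5, 4, 3, 2, 1e-9, 1e-9, 1e-9, 1e-9])
        assert select_rank(s, k=11) == 11

    def test_forced_rank_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_rank(np.array([3.0, 2.0, 1.0]), k=4)


class TestTargetRotation:
    def test_singular_vector_targets_give_diagonal_K(self, noiseless_mixture):
        chrom, _ = noiseless_mixture
        F = svd_factor(chrom)
        m1 = 4
        targets = []
        full = np.zeros(len(F.waxis))
        for j in range(m1):
            prof = full.copy()
            prof[F.observed_rows] = F.U[:, j]
            targets.append(ComponentSpectrum(f"u{j}", F.waxis, prof, kind="baseline"))
        D = target_rotation(F, m1, ComponentLibrary(targets))
        off = D.K - np.diag(np.diag(D.K))
        assert np.max(np.abs(off)) < 1e-10
        # V' columns proportional to V W with the inverse diagonal scale
        ref = F.V[:, :m1] * F.s[:m1]
        np.testing.assert_allclose(D.Vprime * np.diag(D.K), ref, atol=1e-8)

    def test_noiseless_fru_run_recovers_elution_peak_position(
        self, noiseless_fru, spectra
    ):
        chrom, truth = noiseless_fru
        lib = full_library(spectra, ("Fru",))
        D = target_rotation(svd_factor(chrom), 6, lib)
        step = chrom.taxis.values[1] - chrom.taxis.values[0]
        t_rec = chrom.taxis.values[np.argmax(D.curve("Fru"))]
        t_true = chrom.taxis.values[np.argmax(truth.true_series("Fru"))]
        assert abs(t_rec - t_true) <= step

    def test_five_sugar_rotation_matches_targets_and_elution_order(
        self, mixture_decomposition
    ):
        D, _ = mixture_decomposition
        assert np.all(D.fit_residual[:5] < 1e-6)
        centers = [
            D.taxis.values[np.argmax(D.curve(s))] for s in presets.SUGARS
        ]
        assert centers == sorted(centers)  # Fru < Glu < Suc < Mal < Tre

    def test_rotation_conserves_truncated_reconstruction(
        self, mixture_decomposition, noiseless_fru, spectra
    ):
        D, _ = mixture_decomposition
        assert D.reconstruction_error() < 1e-8
        chrom, _ = noiseless_fru
        D2 = target_rotation(svd_factor(chrom), 6, full_library(spectra, ("Fru",)))
        assert D2.reconstruction_error() < 1e-8

    def test_noisy_masked_rotation_still_conserves_product(self, spectra):
        chrom, _ = presets.sugar_mixture_run(
            {s: 25.0 for s in presets.SUGARS}, seed=21, masked=True
        )
        D = target_rotation(svd_factor(chrom), 11, full_library(spectra))
        assert D.reconstruction_error() < 1e-8

    def test_permuting_targets_permutes_components_identically(
        self, noiseless_mixture, spectra
    ):
        chrom, _ = noiseless_mixture
        F = svd_factor(chrom)
        names = list(presets.SUGARS)
        libA = full_library(spectra, tuple(names))
        libB = full_library(spectra, tuple(reversed(names)))
        DA = target_rotation(F, 9, libA)
        DB = target_rotation(F, 9, libB)
        for s in names:
            np.testing.assert_allclose(DA.curve(s), DB.curve(s), atol=1e-9)
            a, b = DA.spectrum(s), DB.spectrum(s)
            np.testing.assert_allclose(a[np.isfinite(a)], b[np.isfinite(b)], atol=1e-9)

    def test_collinear_targets_rejected_by_library(self, waxis):
        s = presets.model_spectra(waxis)["Glu"]
        twin = dataclasses.replace(s, name="Glu-copy")
        with pytest.raises(ValueError, match="collinear"):
            ComponentLibrary([s, twin])

    def test_rank_below_target_count_rejected(self, noiseless_mixture, spectra):
        chrom, _ = noiseless_mixture
        with pytest.raises(ValueError, match="smaller"):
            target_rotation(svd_factor(chrom), 3, full_library(spectra))


class TestNormalizeComponents:
    def test_product_is_preserved_and_curves_have_unit_max(
        self, mixture_decomposition
    ):
        D, _ = mixture_decomposition
        Dn = normalize_components(D)
        rows = D.observed_rows
        before = D.Uprime[rows] @ D.Vprime.T
        after = Dn.Uprime[rows] @ Dn.Vprime.T
        assert np.max(np.abs(after - before)) < 1e-12 * np.max(np.abs(before))
        assert np.allclose(np.max(np.abs(Dn.Vprime), axis=0), 1.0)

    def test_scale_moves_to_spectral_factor(self, mixture_decomposition):
        D, _ = mixture_decomposition
        Dn = normalize_components(D)
        j = 0
        scale = np.max(np.abs(D.Vprime[:, j]))
        rows = D.observed_rows
        np.testing.assert_allclose(
            Dn.Uprime[rows, j], D.Uprime[rows, j] * scale, rtol=1e-12
        )

    def test_zero_component_left_unscaled_with_warning(self, mixture_decomposition):
        D, _ = mixture_decomposition
        Dz = dataclasses.replace(D, Vprime=D.Vprime.copy())
        Dz.Vprime[:, -1] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_components(Dz)
        assert not out.Vprime[:, -1].any()


class TestNoisyParameterRecovery:
    def test_recovered_centers_and_amplitudes_track_ground_truth(self, spectra):
        """Across seeded noisy syntheses (noise = 1% of the strongest analyte
        signal), rotated elution curves reproduce the true peak position and
        amplitude of each sugar."""
        conc = {s: 25.0 for s in presets.SUGARS}
        c_errs, a_errs = [], []
        for seed in range(6):
            chrom, truth = presets.sugar_mixture_run(conc, seed=40 + seed)
            D = target_rotation(svd_factor(chrom), 9, full_library(spectra))
            t = D.taxis.values
            for s in presets.SUGARS:
                rec, tru = D.curve(s), truth.true_series(s)
                c_errs.append(abs(t[np.argmax(rec)] - t[np.argmax(tru)]))
                a_errs.append(abs(rec.max() / tru.max() - 1))
        assert np.median(c_errs) <= 0.1
        assert np.median(a_errs) <= 0.05
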