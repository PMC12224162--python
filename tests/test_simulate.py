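import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from hilicraman import presets
from hilicraman.core import MaskSpec, TimeAxis, WavenumberAxis
from hilicraman.simulate import (
    ElutionProfileSpec,
    apply_mask,
    make_component_spectra,
    make_elution_profile,
    residence_time,
    synthesize_matrix,
)


@pytest.fixture(scope="module")
def waxis256():
    return WavenumberAxis(np.linspace(200, 1800, 256))


class TestComponentSpectra:
    def test_single_band_peaks_at_nearest_channel(self, waxis256):
        s = make_component_spectra([(1130, 10, 1.0)], waxis256)
        assert np.argmax(s.profile) == waxis256.nearest_index(1130)
        assert s.profile.max() == pytest.approx(1.0, abs=1e-2)

    @pytest.mark.parametrize(
        "bands, err",
        [([], "empty"), ([(5000, 10, 1.0)], "outside"), ([(1130, -1, 1.0)], "positive")],
    )
    def test_invalid_band_tables_rejected(self, waxis256, bands, err):
        with pytest.raises(ValueError, match=err):
            make_component_spectra(bands, waxis256)

    def test_derivative_artifact_integrates_to_zero(self, waxis256):
        s = make_component_spectra(
            [(920, 6, 1.0), (1375, 8, 0.5)], waxis256, kind="derivative-artifact"
        )
        integral = np.trapezoid(s.profile, waxis256.values)
        l1 = np.trapezoid(np.abs(s.profile), waxis256.values)
        assert abs(integral) < 1e-6 * l1

    def test_lorentzian_band_shape_available(self, waxis256):
        s = make_component_spectra([(1130, 10, 1.0)], waxis256, shape="lorentzian")
        # Lorentzian wings decay slower than Gaussian
        g = make_component_spectra([(1130, 10, 1.0)], waxis256)
        far = waxis256.nearest_index(1350)
        assert s.profile[far] > g.profile[far]


def emg_reference(t, center, sigma, tau):
    """Closed-form exponentially modified Gaussian (area 1), written out
    independently of the simulator."""
    z = (sigma / tau) - (t - center) / sigma
    return (
        1.0 / (2 * tau)
        * np.exp(0.5 * (sigma / tau) ** 2 - (t - center) / tau)
        * erfc(z / np.sqrt(2))
    )


class TestElutionProfile:
    def test_symmetric_peak_maximum_at_center(self):
        axis = presets.default_time_axis()
        spec = ElutionProfileSpec(center=36.4, width=0.5, tail=0.0, amplitude=1.0)
        y = make_elution_profile(spec, axis)
        assert abs(axis.values[np.argmax(y)] - 36.4) <= (axis.values[1] - axis.values[0])

    def test_zero_amplitude_gives_zero_series(self):
        axis = presets.default_time_axis()
        spec = ElutionProfileSpec(center=36.4, width=0.5, amplitude=0.0)
        assert not make_elution_profile(spec, axis).any()

    def test_tailing_matches_closed_form_and_shifts_mode_late(self):
        dense = TimeAxis(np.linspace(30, 55, 100_000))
        spec = ElutionProfileSpec(center=36.4, width=0.5, tail=1.0, amplitude=1.0)
        y = make_elution_profile(spec, dense)
        ref = spec.width * np.sqrt(2 * np.pi) * emg_reference(
            dense.values, 36.4, 0.5, 1.0
        )
        assert np.allclose(y, ref, rtol=1e-8, atol=1e-12)
        mode = dense.values[np.argmax(ref)]
        assert mode > 36.4
        assert abs(dense.values[np.argmax(y)] - mode) < 1e-3

    def test_area_preserved_under_tailing(self):
        dense = TimeAxis(np.linspace(20, 70, 50_000))
        base = ElutionProfileSpec(center=40.0, width=0.5, tail=0.0, amplitude=2.0)
        tailed = ElutionProfileSpec(center=40.0, width=0.5, tail=0.8, amplitude=2.0)
        a0 = np.trapezoid(make_elution_profile(base, dense), dense.values)
        a1 = np.trapezoid(make_elution_profile(tailed, dense), dense.values)
        assert a1 == pytest.approx(a0, rel=1e-6)

    def test_center_outside_axis_warns_not_errors(self):
        axis = presets.default_time_axis()
        with pytest.warns(UserWarning, match="clipped"):
            make_elution_profile(ElutionProfileSpec(center=70.0, width=0.5), axis)


class TestSynthesize:
    def test_one_component_gives_rank_one(self, waxis256):
        taxis = TimeAxis(np.linspace(30, 55, 60))
        s = make_component_spectra([(1130, 10, 1.0)], waxis256)
        series = make_elution_profile(
            ElutionProfileSpec(center=40, width=0.5, amplitude=1.0), taxis
        )
        chrom, _ = synthesize_matrix([(s, series)], taxis)
        sv = np.linalg.svd(chrom.intensities, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]

    def test_nine_component_noiseless_synthesis_has_rank_nine(self, noiseless_mixture):
        chrom, _ = noiseless_mixture
        sv = np.linalg.svd(chrom.observed_submatrix(), compute_uv=False)
        assert np.sum(sv > 1e-10 * sv[0]) == 9

    def test_fixed_seed_is_bit_reproducible(self):
        conc = {"Fru": 25.0, "Glu": 10.0}
        a, _ = presets.sugar_mixture_run(conc, seed=5)
        b, _ = presets.sugar_mixture_run(conc, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_amplitude_linearity(self):
        """M(2a) - 2 M(a) + M(0) vanishes when noise is off."""
        def run(c):
            chrom, _ = presets.sugar_mixture_run({"Fru": c}, seed=3, noise_sigma=0.0,
                                                 masked=False)
            return chrom.intensities

        resid = run(50.0) - 2 * run(25.0) + run(0.0)
        assert np.max(np.abs(resid)) < 1e-9

    def test_mismatched_series_length_rejected(self, waxis256):
        taxis = TimeAxis(np.linspace(30, 55, 60))
        s = make_component_spectra([(1130, 10, 1.0)], waxis256)
        with pytest.raises(ValueError, match="length"):
            synthesize_matrix([(s, np.zeros(59))], taxis)


class TestMask:
    def test_empty_and_nonoverlapping_masks_are_identity(self, noiseless_mixture):
        chrom, _ = presets.sugar_mixture_run({"Fru": 25.0}, seed=1, noise_sigma=0.0,
                                             masked=False)
        for mask in (MaskSpec([]), MaskSpec([(2200, 2300)])):
            out = apply_mask(chrom, mask)
            np.testing.assert_array_equal(out.intensities, chrom.intensities)
            assert out.observed.all()

    def test_masked_and_unmasked_agree_on_observed_channels(self):
        conc = {s: 25.0 for s in presets.SUGARS}
        full, _ = presets.sugar_mixture_run(conc, seed=9, masked=False)
        masked = apply_mask(full, presets.default_mask())
        rows = masked.observed_rows
        np.testing.assert_array_equal(masked.intensities[rows], full.intensities[rows])

    def test_masked_fraction_equals_interval_coverage(self, waxis256):
        chrom, _ = presets.sugar_mixture_run({"Fru": 25.0}, seed=1, noise_sigma=0.0,
                                             masked=False, waxis=waxis256)
        mask = MaskSpec([(900, 940)])
        out = apply_mask(chrom, mask)
        in_interval = np.sum((waxis256.values >= 900) & (waxis256.values <= 940))
        assert (~out.observed).sum() == in_interval

    def test_total_mask_rejected(self, waxis256):
        chrom, _ = presets.sugar_mixture_run({"Fru": 25.0}, seed=1, noise_sigma=0.0,
                                             masked=False, waxis=waxis256)
        with pytest.raises(ValueError, match="entire"):
            apply_mask(chrom, MaskSpec([(0, 5000)]))


class TestResidenceTime:
    @pytest.mark.parametrize(
        "volume, flow, expected",
        [(0.17, 3.0, 3.4), (1.0, 60.0, 1.0), (0.0424, 3.0, 0.848)],
    )
    def test_worked_examples(self, volume, flow, expected):
        assert residence_time(volume, flow) == pytest.approx(expected)

    @given(
        v=st.floats(1e-3, 1e3, allow_nan=False),
        f=st.floats(1e-3, 1e3, allow_nan=False),
        c=st.floats(1.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scales_linearly_with_volume_and_inversely_with_flow(self, v, f, c):
        t = residence_time(v, f)
        assert residence_time(c * v, f) == pytest.approx(c * t, rel=1e-9)
        assert residence_time(v, c * f) == pytest.approx(t / c, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            residence_time(0.0, 3.0)
        with pytest.raises(ValueError):
            residence_time(0.17, -1.0)
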