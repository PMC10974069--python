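import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafmetal as lm
from leafmetal.cohort import CohortConfig, SpectraSet, generate_cohort
from leafmetal.preprocessing import (PreprocessingError, TRANSFORM_NAMES,
                                     absorbance, apply_transform, derivative,
                                     msc_apply, msc_fit, preprocess, sg_smooth,
                                     snv, trim_low_bands)


def _make(wl, refl):
    refl = np.atleast_2d(np.asarray(refl, float))
    ids = np.array([f"S{i:02d}" for i in range(1, refl.shape[0] + 1)])
    return SpectraSet(site_ids=ids, wavelengths_nm=np.asarray(wl, float),
                      reflectance=refl)


class TestTrim:
    def test_boundary_inclusive(self):
        s = _make([301.0, 379.9, 380.0, 1145.0], [[0.1, 0.2, 0.3, 0.4]])
        out = trim_low_bands(s, 380.0)
        assert np.array_equal(out.wavelengths_nm, [380.0, 1145.0])
        assert np.array_equal(out.reflectance, [[0.3, 0.4]])

    def test_zero_cutoff_is_identity(self, small_spectra):
        out = trim_low_bands(small_spectra, 0.0)
        assert np.array_equal(out.reflectance, small_spectra.reflectance)
        assert np.array_equal(out.wavelengths_nm, small_spectra.wavelengths_nm)

    def test_default_generator_grid_arithmetic(self):
        wl = CohortConfig().wavelength_grid()
        s = _make(wl, np.full((1, wl.size), 0.5))
        out = trim_low_bands(s)
        k = np.arange(wl.size)
        expected = wl[301.0 + 3.3 * k >= 380.0]
        assert np.array_equal(out.wavelengths_nm, expected)

    def test_no_survivors_errors(self, small_spectra):
        with pytest.raises(PreprocessingError):
            trim_low_bands(small_spectra, 1e6)


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        s = _make(400 + np.arange(30), np.full((2, 30), 0.42))
        out = sg_smooth(s, 11, 2)
        assert np.allclose(out.reflectance, 0.42, atol=1e-12)

    def test_quadratic_reproduced(self):
        i = np.arange(40, dtype=float)
        row = 0.3 + 0.01 * i - 2e-4 * i**2
        s = _make(400 + i, row[None, :])
        out = sg_smooth(s, 11, 2)
        assert np.allclose(out.reflectance[0], row, atol=1e-10)

    def test_interior_matches_per_window_least_squares(self, rng):
        n = 41
        row = rng.random(n)
        s = _make(400 + np.arange(n), row[None, :])
        out = sg_smooth(s, 11, 2).reflectance[0]
        half = 5
        pos = np.arange(-half, half + 1, dtype=float)
        V = np.vander(pos, 3, increasing=True)  # 1, x, x^2
        for c in range(half, n - half):
            beta, *_ = np.linalg.lstsq(V, row[c - half:c + half + 1], rcond=None)
            assert out[c] == pytest.approx(beta[0], abs=1e-10)

    @pytest.mark.parametrize("window,poly", [(10, 2), (11, 12), (51, 2)])
    def test_bad_parameters(self, small_spectra, window, poly):
        with pytest.raises(PreprocessingError):
            sg_smooth(small_spectra, window, poly)


class TestAbsorbance:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.3010)])
    def test_values(self, r, expected):
        s = _make([400, 410, 420], np.full((1, 3), r))
        assert absorbance(s).reflectance[0, 0] == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_rejected(self):
        s = SpectraSet(site_ids=np.array(["a"]),
                       wavelengths_nm=np.array([1.0, 2.0]),
                       reflectance=np.array([[0.5, 0.0]]))
        with pytest.raises(PreprocessingError):
            absorbance(s)

    def test_strictly_decreasing_in_reflectance(self, rng):
        r = np.sort(0.01 + 0.98 * rng.random(30))
        s = _make(400 + np.arange(30), r[None, :])
        assert np.all(np.diff(absorbance(s).reflectance[0]) < 0)


class TestDerivative:
    def test_constant_gives_zeros(self):
        s = _make(400 + 3.3 * np.arange(20), np.full((3, 20), 0.7))
        assert np.allclose(derivative(s, 1).reflectance, 0.0, atol=1e-12)
        assert np.allclose(derivative(s, 2).reflectance, 0.0, atol=1e-12)

    def test_linear_slope_recovered_everywhere(self):
        wl = 400 + 3.3 * np.arange(25)
        m = 2.5e-3
        s = _make(wl, (0.1 + m * wl)[None, :])
        fd = derivative(s, 1).reflectance[0]
        sd = derivative(s, 2).reflectance[0]
        assert np.allclose(fd, m, atol=1e-12)
        assert np.allclose(sd, 0.0, atol=1e-12)

    def test_cubic_matches_analytic_to_second_order(self):
        wl = 400 + 3.3 * np.arange(100)
        u = (wl - 560.0) / 100.0
        s = _make(wl, (u**3)[None, :])
        fd = derivative(s, 1).reflectance[0]
        sd = derivative(s, 2).reflectance[0]
        fd_true = 3 * u**2 / 100.0
        sd_true = 6 * u / 100.0**2
        h = 3.3 / 100.0
        # central FD error ~ h^2/6 * f'''; SD is exact for cubics on uniform grids
        assert np.allclose(fd[1:-1], fd_true[1:-1], atol=h**2 * 6 / 100.0)
        assert np.allclose(sd[1:-1], sd_true[1:-1], atol=1e-10)

    def test_linearity(self, rng):
        wl = 400 + 3.3 * np.arange(30)
        x = rng.random(30)
        y = rng.random(30)
        for order in (1, 2):
            lhs = derivative(_make(wl, (2 * x - 3 * y)[None, :]), order).reflectance
            rhs = (2 * derivative(_make(wl, x[None, :]), order).reflectance
                   - 3 * derivative(_make(wl, y[None, :]), order).reflectance)
            assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_few_channels(self):
        s = _make([400.0, 410.0], [[0.1, 0.2]])
        with pytest.raises(PreprocessingError):
            derivative(s, 1)

    def test_bad_order(self, small_spectra):
        with pytest.raises(PreprocessingError):
            derivative(small_spectra, 3)


class TestMSC:
    def test_reference_corrects_to_itself(self, small_spectra):
        ref = msc_fit(small_spectra)
        s = small_spectra.replace(
            reflectance=ref.reference_spectrum[None, :],
            site_ids=np.array(["ref"]))
        out = msc_apply(s, ref)
        assert np.allclose(out.reflectance[0], ref.reference_spectrum, atol=1e-12)

    def test_affine_shift_recovers_reference(self, small_spectra):
        ref = msc_fit(small_spectra)
        shifted = small_spectra.replace(
            reflectance=0.2 + 1.5 * ref.reference_spectrum[None, :],
            site_ids=np.array(["x"]))
        out = msc_apply(shifted, ref)
        assert np.allclose(out.reflectance[0], ref.reference_spectrum, atol=1e-10)

    def test_coefficients_match_normal_equations(self, small_spectra):
        ref = msc_fit(small_spectra)
        out = msc_apply(small_spectra, ref)
        A = np.column_stack([np.ones(small_spectra.n_channels),
                             ref.reference_spectrum])
        for i, x in enumerate(small_spectra.reflectance):
            (a, b), *_ = np.linalg.lstsq(A, x, rcond=None)
            assert np.allclose(out.reflectance[i], (x - a) / b, atol=1e-10)

    def test_zero_slope_errors_with_sample_name(self, small_spectra):
        ref = msc_fit(small_spectra)
        flat = small_spectra.replace(
            reflectance=np.full((1, small_spectra.n_channels), 0.5),
            site_ids=np.array(["FLAT01"]))
        with pytest.raises(PreprocessingError, match="FLAT01"):
            msc_apply(flat, ref)

    def test_needs_two_calibration_spectra(self, small_spectra):
        one = small_spectra.replace(reflectance=small_spectra.reflectance[:1],
                                    site_ids=small_spectra.site_ids[:1])
        with pytest.raises(PreprocessingError):
            msc_fit(one)

    def test_grid_mismatch_rejected(self, small_spectra):
        ref = msc_fit(small_spectra)
        other = _make(500 + 10 * np.arange(20), small_spectra.reflectance)
        with pytest.raises(PreprocessingError):
            msc_apply(other, ref)

    def test_removes_pure_affine_scatter_on_cohort(self):
        cfg = CohortConfig(stress_slope_cd=0, stress_slope_as=0,
                           stress_noise_sd=0, channel_noise_sd=0,
                           scatter_sd_add=0.03, scatter_sd_mult=0.08, seed=2)
        spectra, _ = generate_cohort(cfg)
        out = msc_apply(spectra, msc_fit(spectra)).reflectance
        assert np.all(np.ptp(out, axis=0) < 1e-8)


class TestSNV:
    def test_rows_standardized(self, small_spectra):
        out = snv(small_spectra).reflectance
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_three_point_example(self):
        s = _make([1.0, 2.0, 3.0], [[1.0, 2.0, 3.0]])
        assert np.allclose(snv(s).reflectance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    @given(c=st.floats(-5, 5), g=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, c, g):
        x = np.linspace(0.1, 0.9, 17)
        s1 = _make(400 + np.arange(17), x[None, :])
        s2 = _make(400 + np.arange(17), (c + g * x)[None, :])
        assert np.allclose(snv(s1).reflectance, snv(s2).reflectance, atol=1e-9)

    def test_constant_spectrum_errors(self):
        s = _make([1.0, 2.0, 3.0], [[0.5, 0.5, 0.5]])
        with pytest.raises(PreprocessingError):
            snv(s)


class TestDispatch:
    def test_r_is_identity(self, small_spectra):
        out = apply_transform(small_spectra, "R")
        assert np.array_equal(out.reflectance, small_spectra.reflectance)

    def test_afd_is_derivative_of_absorbance(self, small_spectra):
        a = apply_transform(small_spectra, "AFD").reflectance
        b = derivative(absorbance(small_spectra), 1).reflectance
        assert np.array_equal(a, b)

    def test_asd_is_second_derivative_of_absorbance(self, small_spectra):
        a = apply_transform(small_spectra, "ASD").reflectance
        b = derivative(absorbance(small_spectra), 2).reflectance
        assert np.array_equal(a, b)

    def test_all_transforms_preserve_shape(self, default_cohort):
        spectra, _ = default_cohort
        base = sg_smooth(trim_low_bands(spectra))
        shapes = {name: apply_transform(base, name).reflectance.shape
                  for name in TRANSFORM_NAMES}
        assert set(shapes.values()) == {base.reflectance.shape}

    def test_unknown_name_rejected(self, small_spectra):
        with pytest.raises(PreprocessingError):
            apply_transform(small_spectra, "CR")


class TestPipelineOrder:
    def test_trim_before_smooth_changes_edges(self, rng):
        # wild sub-380 channels must not bleed into the smoothed >=380 region
        wl = 301 + 3.3 * np.arange(100)
        row = 0.4 + 0.01 * rng.standard_normal(100)
        row[wl < 380] += 5.0
        s = _make(wl, row[None, :])
        trimmed_first = sg_smooth(trim_low_bands(s)).reflectance
        smoothed_first = trim_low_bands(sg_smooth(s)).reflectance
        assert not np.allclose(trimmed_first, smoothed_first)

    def test_preprocess_composes_stages(self, default_cohort):
        spectra, _ = default_cohort
        out = preprocess(spectra, "AT")
        manual = apply_transform(sg_smooth(trim_low_bands(spectra)), "AT")
        assert np.array_equal(out.reflectance, manual.reflectance)
        assert out.wavelengths_nm.min() >= 380.0
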