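"""Unit and property tests for the wavelength-domain forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from dsfa_spri import (
    AB_FILTER,
    DEFAULT_DIP,
    DipModel,
    PassbandFilter,
    Spectrum,
    WavelengthGrid,
    band_intensity,
    find_dip,
    fit_gaussian_dip,
    gamma_value,
    make_passband,
    spr_spectrum,
)


def rect_spectrum(grid, lo, hi, height=1.0):
    """Ideal rectangle with half-height edge samples (exact trapezoid area)."""
    lam = grid.values
    samples = np.where((lam > lo) & (lam < hi), height, 0.0)
    samples[np.isclose(lam, lo) | np.isclose(lam, hi)] = 0.5 * height
    return Spectrum(grid, samples)


def flat_spectrum(grid, value=1.0):
    return Spectrum(grid, np.full(len(grid), value))


class TestWavelengthGrid:
    def test_values_are_uniform_and_cover_span(self, grid):
        lam = grid.values
        assert lam[0] == 550.0 and lam[-1] == 610.0
        assert np.allclose(np.diff(lam), 0.1)

    @pytest.mark.parametrize("kwargs", [
        {"lambda_min": 600, "lambda_max": 550, "step": 0.1},
        {"lambda_min": 550, "lambda_max": 600, "step": -1.0},
        {"lambda_min": 550, "lambda_max": 600.05, "step": 0.1},
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WavelengthGrid(**kwargs)


class TestMakePassband:
    def test_a_filter_plateau_exceeds_80_percent(self, grid):
        t = make_passband(583, 598, 0.85, 4.5, grid)
        lam = grid.values
        plateau = (lam >= 588) & (lam <= 593)
        assert np.all(t.samples[plateau] >= 0.8)

    def test_midpoint_equals_peak_and_cuts_equal_half_peak(self, grid):
        t = make_passband(583, 598, 0.85, 4.5, grid)
        lam = grid.values
        assert t.samples[np.isclose(lam, 590.5)][0] == pytest.approx(0.85, abs=1e-12)
        assert t.samples[np.isclose(lam, 583.0)][0] == pytest.approx(0.425, abs=1e-12)
        assert t.samples[np.isclose(lam, 598.0)][0] == pytest.approx(0.425, abs=1e-12)

    def test_edges_are_monotonic(self, grid):
        t = make_passband(583, 598, 0.85, 4.5, grid)
        lam = grid.values
        rising = t.samples[(lam >= 578) & (lam <= 588)]
        falling = t.samples[(lam >= 593) & (lam <= 603)]
        assert np.all(np.diff(rising) >= 0)
        assert np.all(np.diff(falling) <= 0)

    def test_edge_width_spans_50_to_0_005_percent(self, grid):
        t = make_passband(583, 598, 0.85, 4.5, grid)
        lam, vals = grid.values, t.samples
        on_edge = (lam >= 575) & (lam <= 585)
        lam_50 = np.interp(0.5 * 0.85, vals[on_edge], lam[on_edge])
        lam_low = np.interp(5e-5 * 0.85, vals[on_edge], lam[on_edge])
        assert lam_50 - lam_low == pytest.approx(4.5, abs=0.05)

    def test_band_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="exceeds grid span"):
            make_passband(540, 560, 0.85, 4.5, grid)


class TestSprSpectrum:
    def test_minimum_at_lambda0_at_reference_index(self, grid, dip):
        spec = spr_spectrum(dip, dip.n0, grid)
        assert grid.values[np.argmin(spec.samples)] == pytest.approx(dip.lambda0)

    def test_linear_shift_of_minimum(self, grid):
        dip = DipModel(lambda0=590.0, slope_s_lambda=244.7)
        spec = spr_spectrum(dip, dip.n0 + 0.01, grid)
        lam_min = grid.values[np.argmin(spec.samples)]
        assert lam_min == pytest.approx(592.447, abs=grid.step)
        assert dip.dip_center(dip.n0 + 0.01) == pytest.approx(592.447)

    def test_zero_depth_gives_flat_baseline(self, grid):
        dip = DipModel(depth=0.0, baseline=0.9)
        spec = spr_spectrum(dip, dip.n0, grid)
        assert np.allclose(spec.samples, 0.9)

    def test_unphysical_index_rejected(self, grid, dip):
        with pytest.raises(ValueError, match="aqueous range"):
            spr_spectrum(dip, 1.5, grid)


class TestBandIntensity:
    def test_ideal_rectangle_integrates_to_its_width(self, grid):
        filt = rect_spectrum(grid, 580.0, 595.0)
        value = band_intensity(flat_spectrum(grid), filt, flat_spectrum(grid))
        assert value == pytest.approx(15.0, rel=1e-12)

    def test_dip_at_boundary_splits_equally_between_equal_bands(self, grid):
        # symmetric Gaussian dip at 590; ideal equal-width bands on each side
        dip = DipModel(lambda0=590.0, width=6.0)
        refl = spr_spectrum(dip, dip.n0, grid)
        band1 = rect_spectrum(grid, 575.0, 590.0)
        band2 = rect_spectrum(grid, 590.0, 605.0)
        i1 = band_intensity(refl, band1)
        i2 = band_intensity(refl, band2)
        assert i1 == pytest.approx(i2, rel=1e-10)

    def test_gaussian_times_rectangle_matches_erf_closed_form(self):
        # rectangle edges deep in the Gaussian tails so the quadrature is clean
        grid = WavelengthGrid(550.0, 610.0, 0.1)
        amp, center, sigma = 0.7, 581.0, 3.0
        gauss = Spectrum(grid, amp * np.exp(-((grid.values - center) ** 2) / (2 * sigma**2)))
        lo, hi = 560.0, 600.0
        value = band_intensity(gauss, rect_spectrum(grid, lo, hi))
        closed = amp * sigma * np.sqrt(np.pi / 2) * (
            erf((hi - center) / (sigma * np.sqrt(2)))
            - erf((lo - center) / (sigma * np.sqrt(2))))
        assert value == pytest.approx(closed, rel=1e-6)

    def test_mismatched_grids_rejected(self, grid):
        other = WavelengthGrid(550.0, 610.0, 0.2)
        with pytest.raises(ValueError, match="different grids"):
            band_intensity(flat_spectrum(grid), flat_spectrum(other))


class TestGammaValue:
    @pytest.mark.parametrize("i_a, i_ab, expected", [
        (0.5, 1.0, 0.0),   # equal band halves
        (1.0, 1.0, 1.0),   # all intensity in band 1
        (0.6, 1.0, 0.2),
        (0.0, 1.0, -1.0),  # all intensity in band 2
    ])
    def test_reference_values(self, i_a, i_ab, expected):
        assert gamma_value(i_a, i_ab) == pytest.approx(expected, abs=1e-15)

    def test_two_algebraic_forms_agree(self, rng):
        i_ab = rng.uniform(0.1, 10.0, 200)
        i_a = i_ab * rng.uniform(0.0, 1.0, 200)
        i_b = i_ab - i_a
        form1 = (2 * i_a - i_ab) / i_ab
        form2 = (i_a - i_b) / (i_a + i_b)
        assert np.allclose(gamma_value(i_a, i_ab), form1, atol=1e-15)
        assert np.allclose(form1, form2, atol=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gamma_value(0.5, 0.0)

    @given(i_a=st.floats(0.0, 1.0), i_b=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_band_swap(self, i_a, i_b):
        i_ab = i_a + i_b
        if i_ab <= 1e-12:
            return
        assert gamma_value(i_a, i_ab) == pytest.approx(-gamma_value(i_b, i_ab), abs=1e-12)

    @given(i_a=st.floats(0.01, 1.0), i_ab_extra=st.floats(0.01, 1.0),
           c=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, i_a, i_ab_extra, c):
        i_ab = i_a + i_ab_extra
        assert gamma_value(c * i_a, c * i_ab) == pytest.approx(
            gamma_value(i_a, i_ab), rel=1e-9)


class TestFindDip:
    def test_pure_gaussian_dip_located_exactly(self, grid):
        refl = spr_spectrum(DipModel(lambda0=590.0), 1.333, grid)
        loc = find_dip(refl, AB_FILTER)
        assert loc.wavelength == pytest.approx(590.0)
        assert not loc.on_boundary

    def test_dip_outside_band_flagged_at_boundary(self, grid):
        refl = spr_spectrum(DipModel(lambda0=600.0), 1.333, grid)
        loc = find_dip(refl, AB_FILTER)
        assert loc.on_boundary
        assert loc.wavelength == pytest.approx(598.0, abs=grid.step)

    def test_constant_spectrum_rejected(self, grid):
        flat = Spectrum(grid, np.full(len(grid), 0.9))
        with pytest.raises(ValueError, match="constant"):
            find_dip(flat, AB_FILTER)

    def test_refined_estimate_matches_fine_grid_oracle(self, rng):
        """Quadratic refinement lands within half a coarse step of the truth."""
        coarse = WavelengthGrid(550.0, 610.0, 0.5)
        fine = WavelengthGrid(550.0, 610.0, 0.005)  # 100x finer analytic oracle
        dip = DipModel(lambda0=589.12)
        oracle = find_dip(spr_spectrum(dip, dip.n0, fine), AB_FILTER).wavelength
        noisy = Spectrum(coarse, spr_spectrum(dip, dip.n0, coarse).samples
                         + rng.normal(0, 2e-4, len(coarse)))
        refined = find_dip(noisy, AB_FILTER, refine=True).wavelength
        assert abs(refined - oracle) <= 0.5 * coarse.step


class TestFitGaussianDip:
    def test_noiseless_parameters_recovered(self, grid):
        truth = DipModel(lambda0=590.0, width=8.0, depth=0.5, baseline=0.9)
        fit = fit_gaussian_dip(spr_spectrum(truth, truth.n0, grid))
        assert fit.center == pytest.approx(590.0, abs=1e-6)
        assert fit.width == pytest.approx(8.0, abs=1e-6)
        assert fit.depth == pytest.approx(0.5, abs=1e-6)
        assert fit.baseline == pytest.approx(0.9, abs=1e-6)
        assert fit.residual_norm < 1e-9

    def test_noisy_center_recovered_within_tolerance(self, grid, rng):
        truth = DipModel(lambda0=590.0)
        clean = spr_spectrum(truth, truth.n0, grid)
        noisy = Spectrum(grid, clean.samples + rng.normal(0, 0.01, len(grid)))
        fit = fit_gaussian_dip(noisy)
        assert fit.center == pytest.approx(590.0, abs=0.2)

    def test_monotonic_ramp_rejected(self, grid):
        ramp = Spectrum(grid, np.linspace(0.1, 0.9, len(grid)))
        with pytest.raises(ValueError, match="minimum"):
            fit_gaussian_dip(ramp)


class TestRedShiftSign:
    def test_gamma_increases_with_index_at_default_alignment(self, optics):
        """Red shift of the resonance raises gamma across the calibration range."""
        ns = np.linspace(1.333, 1.3495, 20)
        gammas = np.array([optics.gamma(n) for n in ns])
        assert np.all(np.diff(gammas) > 0)

    def test_blue_shift_lowers_gamma_below_aligned_value(self, grid, optics):
        aligned = optics.gamma(DEFAULT_DIP.n0)
        blue = SceneOpticsShifted(-1.0).gamma(DEFAULT_DIP.n0)
        red = SceneOpticsShifted(+1.0).gamma(DEFAULT_DIP.n0)
        assert blue < aligned < red


def SceneOpticsShifted(delta_nm):
    from dsfa_spri import SceneOptics

    return SceneOptics(dip=DEFAULT_DIP.with_center(DEFAULT_DIP.lambda0 + delta_nm))


class TestValidation:
    def test_dip_model_invariants(self):
        with pytest.raises(ValueError):
            DipModel(depth=0.95, baseline=0.9)
        with pytest.raises(ValueError):
            DipModel(width=0.0)

    def test_passband_invariants(self):
        with pytest.raises(ValueError):
            PassbandFilter(598, 583)
        with pytest.raises(ValueError):
            PassbandFilter(583, 598, peak_transmittance=0.0)
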