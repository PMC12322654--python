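"""Nuclear-ensemble spectrum assembly, calibration and band metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from azoswitch.constants import HC_EV_NM
from azoswitch.ensemble_spectra import (
    BandMetrics,
    ExcitationRecord,
    ExperimentalSpectrum,
    WavelengthTrace,
    absorbance_from_epsilon,
    assemble_spectrum,
    band_metrics,
    calibrate_shift,
    cis_trans_split,
    epsilon_from_absorbance,
    to_wavelength,
)
from azoswitch.synthetic_data import gen_experimental_spectrum


def single_line(energy=2.7605, strength=0.1):
    return pd.DataFrame({"energy_eV": [energy], "osc_strength": [strength]})


class TestAssembly:
    def test_single_line_peak_at_hc_over_e(self):
        spec = assemble_spectrum(single_line())
        m = band_metrics(to_wavelength(spec), window=(380, 780))
        assert m.lambda_max == pytest.approx(HC_EV_NM / 2.7605, abs=0.1)

    def test_two_close_lines_merge_to_single_maximum(self):
        df = pd.DataFrame({"energy_eV": [2.58 - 0.01, 2.58 + 0.01], "osc_strength": [0.05, 0.05]})
        spec = assemble_spectrum(df, fwhm=0.15)
        peak_e = spec.energy_ev[np.argmax(spec.intensity)]
        assert peak_e == pytest.approx(2.58, abs=0.003)
        # single maximum: intensity rises then falls
        d = np.diff(spec.intensity)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes == 1

    def test_integral_equals_mean_oscillator_strength(self, rng):
        energies = rng.normal(2.58, 0.08, 6000)
        df = pd.DataFrame({"energy_eV": energies, "osc_strength": np.full(6000, 0.05)})
        spec = assemble_spectrum(df)
        assert spec.integral() == pytest.approx(0.05, rel=1e-3)

    def test_linearity_under_ensemble_union(self, rng):
        a = pd.DataFrame({"energy_eV": rng.normal(2.5, 0.05, 300), "osc_strength": rng.uniform(0.01, 0.1, 300)})
        b = pd.DataFrame({"energy_eV": rng.normal(3.1, 0.05, 100), "osc_strength": rng.uniform(0.01, 0.1, 100)})
        both = assemble_spectrum(pd.concat([a, b], ignore_index=True))
        mix = (300 * assemble_spectrum(a).intensity + 100 * assemble_spectrum(b).intensity) / 400
        np.testing.assert_allclose(both.intensity, mix, rtol=1e-10, atol=1e-14)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            assemble_spectrum(pd.DataFrame({"energy_eV": [], "osc_strength": []}))
        with pytest.raises(ValueError):
            assemble_spectrum(single_line(), fwhm=0.0)
        with pytest.raises(ValueError):
            ExcitationRecord(0, "trans", -1.0, 0.1)
        with pytest.raises(ValueError):
            ExcitationRecord(0, "trans", 2.5, -0.1)
        with pytest.raises(ValueError):
            ExcitationRecord(0, "zap", 2.5, 0.1)

    def test_lines_near_grid_edge_warn(self):
        with pytest.warns(RuntimeWarning):
            assemble_spectrum(single_line(energy=1.52))


class TestWavelengthConversion:
    def test_constant(self):
        spec = assemble_spectrum(single_line(2.7))
        trace = to_wavelength(spec)
        assert trace.wavelength_nm.min() == pytest.approx(HC_EV_NM / 4.5, rel=1e-9)
        assert HC_EV_NM / 2.0 == pytest.approx(619.921, abs=1e-3)

    def test_no_jacobian_round_trip(self):
        spec = assemble_spectrum(single_line())
        trace = to_wavelength(spec, jacobian=False)
        # back-conversion: intensities are carried as-is
        back_e = HC_EV_NM / trace.wavelength_nm[::-1]
        np.testing.assert_allclose(back_e, spec.energy_ev, rtol=1e-12)
        np.testing.assert_allclose(trace.intensity[::-1], spec.intensity, rtol=0, atol=0)

    def test_jacobian_moves_band_maximum_blueward(self):
        # for a Gaussian I(E) centered at E0, E^2*I(E) peaks near E0 + 2 sigma^2/E0
        e0, fwhm = 2.58, 0.3
        sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
        spec = assemble_spectrum(single_line(e0), fwhm=fwhm)
        lam_plain = band_metrics(to_wavelength(spec, jacobian=False)).lambda_max
        lam_jac = band_metrics(to_wavelength(spec, jacobian=True)).lambda_max
        assert lam_jac < lam_plain
        expected = HC_EV_NM / (e0 + 2 * sigma**2 / e0)
        assert lam_jac == pytest.approx(expected, abs=0.5)


class TestCalibration:
    @pytest.fixture(scope="class")
    @staticmethod
    def base_spec():
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"energy_eV": rng.normal(2.58, 0.08, 2000), "osc_strength": np.full(2000, 0.05)}
        )
        return assemble_spectrum(df)

    def test_identity_gives_zero_shift_unit_scale(self, base_spec):
        exp = gen_experimental_spectrum(base_spec, shift_ev=0.0, seed=0)
        shift, scale, shifted = calibrate_shift(base_spec, exp)
        assert abs(shift) < 2e-3
        assert scale == pytest.approx(1.0, rel=1e-3)
        assert shifted.shift == pytest.approx(shift)

    def test_planted_shift_recovered(self, base_spec):
        exp = gen_experimental_spectrum(base_spec, shift_ev=0.15, seed=1)
        shift, _, _ = calibrate_shift(base_spec, exp)
        assert shift == pytest.approx(0.15, abs=2e-3)

    def test_multiplicative_noise_tolerated(self, base_spec):
        exp = gen_experimental_spectrum(base_spec, shift_ev=-0.12, multiplicative_sd=0.05, seed=3)
        shift, _, _ = calibrate_shift(base_spec, exp)
        assert shift == pytest.approx(-0.12, abs=0.01)

    def test_non_overlapping_window_raises(self, base_spec):
        exp = gen_experimental_spectrum(base_spec, seed=0)
        with pytest.raises(ValueError):
            calibrate_shift(base_spec, exp, window=(1000.0, 1100.0))


class TestBandMetrics:
    def gaussian_trace(self, center=455.0, sigma=20.0):
        lam = np.arange(380.0, 781.0, 0.25)
        return WavelengthTrace(lam, np.exp(-0.5 * ((lam - center) / sigma) ** 2))

    def test_gaussian_band_maximum(self):
        m = band_metrics(self.gaussian_trace())
        assert m.lambda_max == pytest.approx(455.0, abs=0.01)

    def test_threshold_one_gives_tail_at_maximum(self):
        m = band_metrics(self.gaussian_trace(), threshold_fraction=1.0)
        assert m.tail_extent == pytest.approx(m.lambda_max, abs=0.3)

    def test_tail_extent_closed_form(self):
        sigma = 20.0
        m = band_metrics(self.gaussian_trace(sigma=sigma), threshold_fraction=0.01)
        assert m.tail_extent == pytest.approx(455.0 + sigma * math.sqrt(2 * math.log(100)), abs=0.3)

    def test_flat_trace_rejected(self):
        lam = np.arange(380.0, 781.0, 1.0)
        with pytest.raises(ValueError):
            band_metrics(WavelengthTrace(lam, np.ones_like(lam)))

    def test_metrics_invariants(self):
        with pytest.raises(ValueError):
            BandMetrics(lambda_max=500.0, intensity_max=1.0, tail_extent=450.0)


class TestSplitAndBeerLambert:
    def test_reported_band_positions_give_42nm_split(self):
        cis = BandMetrics(439.0, 1.0, 600.0)
        trans = BandMetrics(481.0, 1.0, 700.0)
        assert cis_trans_split(cis, trans) == pytest.approx(42.0)
        assert cis_trans_split(cis, cis) == 0.0

    def test_synthetic_trans_red_shift_yields_positive_split(self):
        from azoswitch.synthetic_data import PROFILES, gen_ensemble

        specs = {}
        for isomer in ("cis", "trans"):
            _, table = gen_ensemble(PROFILES["dfdc-like"], isomer, n=1500, seed=2, build_frames=False)
            spec = assemble_spectrum(table[["energy_eV", "osc_strength"]].rename(columns={}), fwhm=0.15)
            specs[isomer] = band_metrics(to_wavelength(spec))
        assert cis_trans_split(specs["cis"], specs["trans"]) > 0

    def test_epsilon_arithmetic_and_round_trip(self):
        lam = np.array([440.0, 450.0, 460.0])
        spec = ExperimentalSpectrum(lam, np.array([0.5, 0.0, 0.25]), concentration=5e-4, path_length=1.0)
        eps = epsilon_from_absorbance(spec)
        assert eps[0] == pytest.approx(1000.0)
        assert eps[1] == 0.0
        back = absorbance_from_epsilon(lam, eps, 5e-4, 1.0)
        np.testing.assert_allclose(back.absorbance, spec.absorbance, rtol=1e-12)

    def test_missing_metadata_rejected(self):
        spec = ExperimentalSpectrum(np.array([400.0, 401.0]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            epsilon_from_absorbance(spec)
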