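"""Photoswitching simulation, PSS, quantum yields and decay fitting."""

import math
import warnings

import numpy as np
import pytest

from azoswitch.photokinetics import (
    DecayModel,
    FitError,
    IsomerRatio,
    KineticTrace,
    PhotokineticModel,
    estimate_quantum_yield,
    fit_bi_decay,
    fit_decay,
    fit_mono_decay,
    halflife_report,
    pss_closed_form,
    simulate_photoswitching,
)
from azoswitch.synthetic_data import (
    GSH_BI_PRESET,
    gen_trace,
)
from azoswitch.thermokinetics import Temperature


def make_model(**kw):
    defaults = dict(
        phi_tc=0.005, phi_ct=0.01, eps_t=35.0, eps_c=2.0,
        photon_flux=3e-4, path_length=1.0, k_thermal=0.0, total_conc=5e-4,
    )
    defaults.update(kw)
    return PhotokineticModel(**defaults)


class TestIsomerRatio:
    def test_ratio_construction(self):
        r = IsomerRatio.from_ratio(8, 92)
        assert r.cis_fraction == pytest.approx(0.92)
        assert r.trans_fraction + r.cis_fraction == pytest.approx(1.0)

    @pytest.mark.parametrize("t, c", [(0.5, 0.6), (-0.1, 1.1), (0.9, 0.2)])
    def test_invalid_fractions_rejected(self, t, c):
        with pytest.raises(ValueError):
            IsomerRatio(t, c)


class TestSimulation:
    def test_dark_without_relaxation_is_constant(self):
        model = make_model(k_thermal=0.0)
        trace = simulate_photoswitching(model, [(100.0, False)], IsomerRatio.from_cis(0.4))
        np.testing.assert_allclose(trace.signal, 0.4, atol=1e-12)

    def test_dark_relaxation_is_exponential(self):
        k = 1e-3
        model = make_model(k_thermal=k)
        trace = simulate_photoswitching(model, [(5000.0, False)], IsomerRatio.from_cis(1.0))
        np.testing.assert_allclose(trace.signal, np.exp(-k * trace.times), rtol=1e-12)

    def test_fractions_conserved_and_bounded(self):
        model = make_model(k_thermal=1e-4)
        trace = simulate_photoswitching(model, [(2000.0, True), (2000.0, False)])
        assert ((trace.signal >= -1e-9) & (trace.signal <= 1 + 1e-9)).all()

    def test_long_time_limit_matches_closed_form_pss(self):
        model = make_model(k_thermal=2e-5, eps_t=20.0, eps_c=1.0)
        trace = simulate_photoswitching(
            model, [(4e5, True)], optically_thin=True, points_per_segment=400
        )
        assert trace.signal[-1] == pytest.approx(
            pss_closed_form(model).cis_fraction, abs=1e-6
        )

    def test_exact_ode_close_to_thin_limit_when_weakly_absorbing(self):
        model = make_model(k_thermal=2e-5, eps_t=20.0, eps_c=1.0)  # A_irr = 0.01
        trace = simulate_photoswitching(model, [(4e5, True)], points_per_segment=400)
        assert trace.signal[-1] == pytest.approx(
            pss_closed_form(model).cis_fraction, abs=2e-3
        )

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_photoswitching(make_model(), [])
        with pytest.raises(ValueError):
            simulate_photoswitching(make_model(), [(-5.0, True)])


class TestPSS:
    def test_balanced_rates_give_fifty_fifty(self):
        model = make_model(phi_tc=0.01, phi_ct=0.01, eps_t=10.0, eps_c=10.0)
        assert pss_closed_form(model).cis_fraction == pytest.approx(0.5)

    def test_non_absorbing_cis_is_absorbing_state(self):
        model = make_model(eps_c=0.0)
        assert pss_closed_form(model).cis_fraction == pytest.approx(1.0)

    def test_all_rates_zero_rejected(self):
        model = make_model(phi_tc=0.0, phi_ct=0.0, k_thermal=0.0)
        with pytest.raises(ValueError):
            pss_closed_form(model)

    def test_deep_red_tail_irradiation_gives_cis_rich_pss(self):
        # strong trans tail absorption, nearly transparent cis: the PSS is
        # cis-rich even though the quantum yield is small
        model = make_model(phi_tc=0.0013, phi_ct=0.01, eps_t=35.0, eps_c=0.5)
        assert pss_closed_form(model).cis_fraction > 0.85

    def test_thermal_relaxation_shifts_pss_toward_trans(self):
        lit = make_model(phi_tc=0.005, phi_ct=0.001, eps_t=30.0, eps_c=3.0)
        relaxing = make_model(
            phi_tc=0.005, phi_ct=0.001, eps_t=30.0, eps_c=3.0, k_thermal=1e-4
        )
        assert (
            pss_closed_form(relaxing).cis_fraction < pss_closed_form(lit).cis_fraction
        )


class TestQuantumYield:
    def test_planted_yield_recovered(self, qy_experiment):
        e = qy_experiment
        est = estimate_quantum_yield(
            e.trace, e.anchors, e.photon_flux_einstein_per_s, e.volume_liters,
            e.absorbance_irr, e.total_conc, conversion_window=e.conversion_window,
        )
        assert est.phi == pytest.approx(e.phi_true, rel=0.05)
        assert est.a_trans == pytest.approx(0.10, abs=0.01)
        assert est.a_cis == pytest.approx(0.40, abs=0.02)

    def test_zero_photon_flux_rejected(self, qy_experiment):
        e = qy_experiment
        with pytest.raises(ValueError):
            estimate_quantum_yield(
                e.trace, e.anchors, 0.0, e.volume_liters, e.absorbance_irr, e.total_conc
            )

    def test_insufficient_anchors_rejected(self, qy_experiment):
        e = qy_experiment
        with pytest.raises(ValueError):
            estimate_quantum_yield(
                e.trace, e.anchors[:1], e.photon_flux_einstein_per_s,
                e.volume_liters, e.absorbance_irr, e.total_conc,
            )

    def test_estimate_invariant_under_flux_rescaling(self):
        """Doubling the photon flux doubles the conversion rate but leaves
        the quantum-yield estimate unchanged."""
        results = {}
        for mult in (1.0, 2.0):
            q_p = 6.08e-7 * mult
            conc, vol = 5e-4, 0.002
            model = PhotokineticModel(
                phi_tc=0.00446, phi_ct=0.01, eps_t=35.0, eps_c=2.0,
                photon_flux=q_p / vol, total_conc=conc,
            )
            sim = simulate_photoswitching(model, [(30000.0 / mult, True)], points_per_segment=3000)
            a = 0.10 * (1 - sim.signal) + 0.40 * sim.signal
            trace = KineticTrace(sim.times, a)
            anchors = [
                (t, IsomerRatio.from_cis(float(np.interp(t, sim.times, sim.signal))))
                for t in (0.0, 10000.0 / mult, 29000.0 / mult)
            ]
            est = estimate_quantum_yield(
                trace, anchors, q_p, vol, model.absorbance_irr(0.0), conc,
                conversion_window=0.15,
            )
            results[mult] = est.phi
        assert results[2.0] == pytest.approx(results[1.0], rel=0.01)


class TestMonoFit:
    def test_noiseless_trace_recovered_exactly(self):
        k = 1e-3
        times = np.linspace(0, 3 * math.log(2) / k, 60)
        trace = gen_trace("mono", {"k": k, "amplitude": 0.8, "offset": 0.1}, times)
        fit = fit_mono_decay(trace)
        assert fit.rates[0] == pytest.approx(k, rel=1e-9)
        assert fit.offset == pytest.approx(0.1, abs=1e-9)

    def test_noisy_trace_within_five_percent(self):
        k = 1e-3
        times = np.linspace(0, 3 * math.log(2) / k, 50)
        trace = gen_trace("mono", {"k": k}, times, noise_sd=0.02, seed=1)
        fit = fit_mono_decay(trace)
        assert fit.rates[0] == pytest.approx(k, rel=0.05)

    def test_fixed_offset_improves_precision(self):
        k = 1e-3
        times = np.linspace(0, 4 * math.log(2) / k, 50)
        errs_free, errs_fixed = [], []
        for seed in range(30):
            trace = gen_trace("mono", {"k": k}, times, noise_sd=0.02, seed=seed)
            errs_free.append(fit_mono_decay(trace).rates[0] / k - 1)
            errs_fixed.append(fit_mono_decay(trace, fixed_offset=0.0).rates[0] / k - 1)
        assert np.std(errs_fixed) < np.std(errs_free)

    def test_constant_trace_rejected(self):
        trace = KineticTrace(np.arange(10.0), np.ones(10))
        with pytest.raises(FitError):
            fit_mono_decay(trace)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mono_decay(KineticTrace(np.arange(3.0), np.array([3.0, 2.0, 1.0])))


class TestBiFit:
    def test_noiseless_preset_recovered(self):
        times = np.arange(0, 960.0, 2.0) * 60
        trace = gen_trace("bi", GSH_BI_PRESET, times)
        fit = fit_bi_decay(trace)
        assert fit.model is DecayModel.bi
        halves = sorted(h.to("min") for h in fit.half_lives)
        assert halves[0] == pytest.approx(20.0, rel=1e-6)
        assert halves[1] == pytest.approx(160.0, rel=1e-6)

    def test_noisy_preset_within_ten_percent(self):
        times = np.arange(0, 960.0, 1.0) * 60
        trace = gen_trace("bi", GSH_BI_PRESET, times, noise_sd=0.02, seed=0)
        fit = fit_bi_decay(trace)
        halves = sorted(h.to("min") for h in fit.half_lives)
        assert halves[0] == pytest.approx(20.0, rel=0.10)
        assert halves[1] == pytest.approx(160.0, rel=0.10)

    def test_pure_mono_data_selects_mono(self):
        times = np.linspace(0, 20000.0, 100)
        trace = gen_trace("mono", {"k": 3e-4}, times, noise_sd=0.01, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_bi_decay(trace)
        assert fit.model is DecayModel.mono
        assert fit.rates[0] == pytest.approx(3e-4, rel=0.1)

    def test_degenerate_amplitudes_reduce_to_mono_rate(self):
        params = dict(GSH_BI_PRESET, a_fast=1.0, a_slow=0.0)
        times = np.arange(0, 200.0, 2.0) * 60
        trace = gen_trace("bi", params, times, noise_sd=0.001, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_bi_decay(trace)
        assert min(fit.rates) == pytest.approx(params["k_fast"], rel=0.05) or max(
            fit.rates
        ) == pytest.approx(params["k_fast"], rel=0.05)

    def test_fit_decay_dispatch(self):
        times = np.linspace(0, 10000.0, 50)
        trace = gen_trace("mono", {"k": 5e-4}, times, noise_sd=0.005, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assert fit_decay(trace, "auto").rates[0] == pytest.approx(5e-4, rel=0.05)
        with pytest.raises(ValueError):
            fit_decay(trace, "tri")


class TestHalfLifeReport:
    def test_bridges_to_activation_barrier(self):
        k = math.log(2) / 11376.0  # 3.16 h
        times = np.linspace(0, 40000.0, 60)
        trace = gen_trace("mono", {"k": k}, times)
        fit = fit_mono_decay(trace)
        t_half, barrier = halflife_report(fit, Temperature(328.15))
        assert t_half.to("h") == pytest.approx(3.16, rel=1e-6)
        assert round(barrier.delta_g, 1) == 25.6

    def test_bi_fit_reports_slow_phase(self):
        times = np.arange(0, 960.0, 2.0) * 60
        trace = gen_trace("bi", GSH_BI_PRESET, times)
        fit = fit_bi_decay(trace)
        t_half, _ = halflife_report(fit, Temperature(310.15))
        assert t_half.to("min") == pytest.approx(160.0, rel=1e-6)
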