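"""Anisotropy, quantum yield, lifetime arithmetic and TCSPC fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lovkit as lk
from lovkit.exceptions import DegenerateDataError, FitError, InputError
from lovkit.fluorescence import compare_component_counts
from lovkit.simulate import (
    gen_anisotropy_series,
    gen_decay_histogram,
    gen_polarized,
)


class TestGFactor:
    def test_scalar_ratios(self):
        assert lk.g_factor(1.0, 1.0) == 1.0
        assert lk.g_factor(1.2, 1.0) == pytest.approx(1.2)

    def test_spectral_input_reduces_to_mean_of_pointwise_ratio(self):
        hv = np.array([1.0, 2.0, 3.0])
        hh = np.array([1.0, 1.0, 2.0])
        assert lk.g_factor(hv, hh) == pytest.approx(
            np.mean(hv / hh)
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(InputError):
            lk.g_factor(1.0, 0.0)


class TestSteadyAnisotropy:
    def test_isotropic_case_is_zero(self):
        p = lk.PolarizedIntensities(1.1, 1.0, 1.1, 1.0)
        assert lk.steady_anisotropy(p, g=1.1) == pytest.approx(0.0)

    def test_fully_polarized_limit_is_one(self):
        p = lk.PolarizedIntensities(2.0, 0.0, 1.0, 1.0)
        assert lk.steady_anisotropy(p, g=1.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        p = lk.PolarizedIntensities(1.9, 1.0, 1.1, 1.0)
        assert lk.steady_anisotropy(p, g=1.1) == pytest.approx(
            0.8 / 4.1
        )

    def test_inverts_generator_exactly_at_zero_noise(self):
        for r_true in (0.03, 0.27, 0.28, 0.35):
            p, truth = gen_polarized(r_true=r_true, g_true=1.1)
            g = lk.g_factor(p.i_hv, p.i_hh)
            assert g == pytest.approx(truth["g"], rel=1e-12)
            assert lk.steady_anisotropy(p, g) == pytest.approx(
                r_true, abs=1e-12
            )

    def test_noisy_replicates_unbiased(self):
        rs = []
        for rep in range(100):
            p, _ = gen_polarized(r_true=0.35, noise=0.01, seed=500 + rep)
            rs.append(lk.steady_anisotropy(p, lk.g_factor(p.i_hv, p.i_hh)))
        assert np.mean(rs) == pytest.approx(0.35, abs=0.01)

    @settings(derandomize=True, max_examples=200)
    @given(
        i_vv=st.floats(0.0, 1e6),
        i_vh=st.floats(0.0, 1e6),
        g=st.floats(0.01, 10.0),
    )
    def test_bounded_for_nonnegative_intensities(self, i_vv, i_vh, g):
        p = lk.PolarizedIntensities(i_vv, i_vh, 1.0, 1.0)
        denom = i_vv + 2 * g * i_vh
        if denom <= 0:
            with pytest.raises(InputError):
                lk.steady_anisotropy(p, g)
        else:
            r = lk.steady_anisotropy(p, g)
            # open at -0.5 in exact arithmetic; closed under float underflow
            assert -0.5 <= r <= 1.0

    def test_band_average(self):
        w = np.arange(490.0, 530.0, 1.0)
        r = np.linspace(0.2, 0.4, w.size)
        avg = lk.band_averaged_anisotropy(w, r, center=500.0, half_width=5.0)
        mask = (w >= 495) & (w <= 505)
        assert avg == pytest.approx(r[mask].mean())


class TestRelativeQuantumYield:
    def test_identical_sample_returns_reference_yield(self):
        assert lk.relative_quantum_yield(100.0, 100.0, 0.05, 0.05) == 0.26

    def test_table_scale_example(self):
        phi = lk.relative_quantum_yield(53.85, 100.0, 0.05, 0.05)
        assert phi == pytest.approx(0.140, abs=0.001)

    def test_ratio_invariance(self):
        a = lk.relative_quantum_yield(50.0, 100.0, 0.05, 0.05)
        b = lk.relative_quantum_yield(100.0, 100.0, 0.10, 0.05)
        assert a == pytest.approx(b, rel=1e-12)

    def test_high_absorbance_warns(self):
        with pytest.warns(UserWarning, match="inner-filter"):
            lk.relative_quantum_yield(1.0, 1.0, 0.5, 0.05)


class TestLifetimeArithmetic:
    def test_single_component(self):
        assert lk.fractional_contributions([2.0], [3.3]).tolist() == [1.0]
        assert lk.average_lifetime([3.3], [1.0]) == 3.3

    def test_hand_example(self):
        f = lk.fractional_contributions([0.5, 0.5], [1.0, 3.0])
        assert np.allclose(f, [0.25, 0.75])

    def test_uniform_tau_reduces_to_amplitude_fractions(self):
        alpha = np.array([0.2, 0.3, 0.5])
        f = lk.fractional_contributions(alpha, [2.0, 2.0, 2.0])
        assert np.allclose(f, alpha / alpha.sum())

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=1, max_size=4),
        st.integers(0, 2**31 - 1),
    )
    def test_round_trip_alpha_recovery(self, taus, seed):
        rng = np.random.default_rng(seed)
        alpha = rng.random(len(taus)) + 0.05
        tau = np.asarray(taus)
        f = lk.fractional_contributions(alpha, tau)
        # inverting f_i = alpha_i tau_i / sum recovers alpha up to scale
        alpha_back = f / tau
        ratio = alpha_back / alpha
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_tau_av_monotone_in_each_tau(self):
        f = np.array([0.5, 0.3, 0.2])
        tau = np.array([0.1, 1.0, 3.0])
        base = lk.average_lifetime(tau, f)
        for i in range(3):
            bumped = tau.copy()
            bumped[i] *= 1.5
            assert lk.average_lifetime(bumped, f) > base

    def test_off_unity_fraction_sum_renormalised_with_warning(self):
        with pytest.warns(UserWarning, match="renormalis"):
            out = lk.average_lifetime([1.0, 2.0], [0.52, 0.485])
        assert out == pytest.approx(
            (0.52 * 1 + 0.485 * 2) / 1.005
        )
        with pytest.raises(InputError):
            lk.average_lifetime([1.0, 2.0], [0.6, 0.6])


class TestDecayFit:
    def test_noiseless_single_exponential_exact(self):
        hist, _ = gen_decay_histogram(
            tau=[4.57], alpha=[1.0], irf_fwhm=0.0, total_counts=1e6,
            poisson=False,
        )
        fit = lk.fit_decay(hist, 1)
        assert fit.tau[0] == pytest.approx(4.57, rel=1e-6)
        assert not fit.chi2_defined

    def test_three_component_table_scale_recovery(self, table3_decay_fit):
        fit, truth = table3_decay_fit
        assert fit.n_components == 3
        for est, true in zip(fit.tau, truth["tau"]):
            assert abs(est - true) / true < 0.10
        for est, true in zip(fit.f, truth["f"]):
            assert abs(est - true) < 0.03
        assert fit.tau_av == pytest.approx(truth["tau_av"], rel=0.05)
        assert fit.chi2_reduced < 1.5

    def test_pure_noise_rejected_or_flagged(self):
        rng = np.random.default_rng(99)
        t = np.arange(512) * 0.05
        counts = rng.poisson(2000.0, 512).astype(float)
        irf = np.zeros(512)
        irf[10] = 1e5
        hist = lk.DecayHistogram(t, counts, irf)
        try:
            fit = lk.fit_decay(hist, 2)
        except (FitError, DegenerateDataError):
            return
        assert fit.chi2_reduced > 2.0

    def test_tail_fit_mode_single_exponential(self):
        hist, _ = gen_decay_histogram(
            tau=[2.5], alpha=[1.0], irf_fwhm=0.3, total_counts=2e6, seed=7
        )
        fit = lk.fit_decay(hist, 1, reconvolve=False)
        assert fit.tau[0] == pytest.approx(2.5, rel=0.02)
        assert not fit.reconvolved

    def test_component_count_comparison_helper(self):
        hist, _ = gen_decay_histogram(
            tau=[0.4, 3.0], f=[0.5, 0.5], total_counts=2e6, seed=31
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            one, two, justified = compare_component_counts(
                hist, n_low=1, n_high=2
            )
        assert justified
        assert two.chi2_reduced < one.chi2_reduced

    def test_replicate_recovery_at_reference_counts(self):
        # median over replicates stays inside the single-shot tolerances
        truth_tau = np.array([0.05, 1.2, 3.37])
        tau_errs, f_errs = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(6):
                hist, truth = gen_decay_histogram(
                    tau=truth_tau.tolist(), f=[0.52, 0.097, 0.383],
                    total_counts=5e6, seed=300 + rep,
                )
                fit = lk.fit_decay(hist, 3)
                tau_errs.append(np.abs(fit.tau - truth_tau) / truth_tau)
                f_errs.append(np.abs(fit.f - np.asarray(truth["f"])))
        assert np.all(np.median(tau_errs, axis=0) < 0.10)
        assert np.all(np.median(f_errs, axis=0) < 0.03)

    def test_invalid_component_count(self):
        hist, _ = gen_decay_histogram(
            tau=[1.0], alpha=[1.0], total_counts=1e5, seed=1
        )
        with pytest.raises(InputError):
            lk.fit_decay(hist, 0)
        with pytest.raises(InputError):
            lk.fit_decay(hist, 5)

    def test_summary_reports_components(self, table3_decay_fit):
        fit, _ = table3_decay_fit
        text = fit.summary()
        assert "tau_av" in text and "chi^2" in text


class TestAnisotropyDecay:
    def test_noiseless_recovery(self):
        t, r, truth = gen_anisotropy_series(r0=0.4, theta=1.06)
        fit = lk.fit_anisotropy_decay(t, r)
        assert fit.r0 == pytest.approx(0.4, rel=1e-3)
        assert fit.theta == pytest.approx(1.06, rel=1e-3)

    def test_constant_series_unresolvable(self):
        t = np.arange(0.0, 5.0, 0.1)
        with pytest.raises(DegenerateDataError, match="unresolvable"):
            lk.fit_anisotropy_decay(t, np.full(t.size, 0.3))

    def test_noisy_series_within_five_percent(self):
        t, r, _ = gen_anisotropy_series(
            r0=0.4, theta=1.06, noise=0.02, seed=13
        )
        fit = lk.fit_anisotropy_decay(t, r)
        assert fit.theta == pytest.approx(1.06, rel=0.05)


class TestPerrin:
    def test_half_depolarised_identity(self):
        assert lk.perrin_rotational_time(2.36, 0.4, 0.2) == pytest.approx(
            2.36
        )

    def test_direct_evaluation_at_reported_magnitudes(self):
        theta = lk.perrin_rotational_time(2.36, 0.4, 0.27)
        assert theta == pytest.approx(2.36 / (0.4 / 0.27 - 1.0), rel=1e-12)
        assert theta == pytest.approx(4.90, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(InputError):
            lk.perrin_rotational_time(2.36, 0.4, 0.4)
        with pytest.raises(InputError):
            lk.perrin_rotational_time(2.36, 0.4, 0.5)
        with pytest.raises(InputError):
            lk.perrin_rotational_time(-1.0, 0.4, 0.2)
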