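"""Decay fitting, the depletion binding solver, and titration fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptckin.simulate import GeneratorConfig, gen_decay_trace, gen_titration_series
from ptckin.termination import (
    AnisotropyTrace,
    FitError,
    fit_decay,
    fit_titration,
    predict_rate,
    select_model,
    solve_bound_complex,
)


def bisection_oracle(R, P, K, n, tol=1e-12):
    """Independent root finder: plain interval bisection on the residual."""
    lo, hi = 0.0, min(P, R / n)
    if hi == 0.0:
        return 0.0

    def g(r):
        return K**n * r - (R - n * r) ** n * (P - r)

    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestDecay:
    def test_exact_single_exponential_recovery(self):
        t = np.linspace(0, 30, 61)
        trace = AnisotropyTrace(time=t, signal=0.30 + 0.10 * np.exp(-0.15 * t))
        fit = fit_decay(trace, model="single_exponential")
        assert fit.k_obs == pytest.approx(0.15, abs=1e-9)
        assert fit.asymptote == pytest.approx(0.30, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.10, abs=1e-9)

    def test_biphasic_recovery_and_fast_phase_reported(self):
        trace = gen_decay_trace(0.5, k_slow=0.05, fast_fraction=0.5, noise_sd=0.0)
        fit = fit_decay(trace, model="auto")
        assert fit.model == "biphasic"
        assert fit.k_obs == pytest.approx(0.5, rel=1e-4)
        assert fit.fast_fraction == pytest.approx(0.5, abs=1e-3)
        assert fit.k_fast >= fit.k_slow

    def test_auto_keeps_single_for_monophasic_noisy_data(self, rng):
        trace = gen_decay_trace(0.2, noise_sd=0.005, rng=rng)
        fit = fit_decay(trace, model="auto")
        assert fit.model == "single_exponential"

    def test_monte_carlo_rate_recovery_and_ci_coverage(self, rng):
        """Noisy decays: mean recovered rate within 5%, ~95% CI covers truth."""
        k_true = 0.2
        ks, covered = [], 0
        n_rep = 200
        for _ in range(n_rep):
            trace = gen_decay_trace(k_true, noise_sd=0.005, rng=rng)
            fit = fit_decay(trace, model="single_exponential")
            ks.append(fit.k_obs)
            lo = fit.k_obs - 1.96 * fit.k_fast_se
            hi = fit.k_obs + 1.96 * fit.k_fast_se
            covered += lo <= k_true <= hi
        assert np.mean(ks) == pytest.approx(k_true, rel=0.05)
        assert covered / n_rep >= 0.90

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            AnisotropyTrace(time=np.arange(4.0), signal=np.zeros(4))


class TestBindingSolver:
    def test_no_ligand(self):
        bs = solve_bound_complex(0.0, 50.0, 10.0, 1)
        assert bs.rp5 == 0.0 and bs.rfc_free == 0.0 and bs.p5_free == 50.0

    def test_no_receptor(self):
        bs = solve_bound_complex(100.0, 0.0, 10.0, 2)
        assert bs.rp5 == 0.0 and bs.rfc_free == 100.0

    @pytest.mark.parametrize("R,P,K,n", [(100.0, 50.0, 10.0, 1),
                                         (35.0, 50.0, 28.0, 2)])
    def test_matches_bisection_oracle(self, R, P, K, n):
        bs = solve_bound_complex(R, P, K, n)
        assert bs.rp5 == pytest.approx(bisection_oracle(R, P, K, n), abs=1e-9)
        assert bs.rfc_free == pytest.approx(R - n * bs.rp5, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_bound_complex(-1.0, 50.0, 10.0, 1)
        with pytest.raises(ValueError):
            solve_bound_complex(10.0, 50.0, 0.0, 1)
        with pytest.raises(ValueError):
            solve_bound_complex(10.0, 50.0, 10.0, 3)

    @settings(max_examples=200, deadline=None)
    @given(
        R=st.floats(0.0, 500.0),
        P=st.floats(0.0, 200.0),
        K=st.floats(0.01, 1e4),
        n=st.sampled_from([1, 2]),
    )
    def test_conservation_and_physical_interval(self, R, P, K, n):
        bs = solve_bound_complex(R, P, K, n)
        assert 0.0 <= bs.rp5 <= min(P, R / n) + 1e-12
        assert bs.rfc_free + n * bs.rp5 == pytest.approx(R, abs=1e-9)
        assert bs.p5_free + bs.rp5 == pytest.approx(P, abs=1e-9)

    def test_weak_binding_limit_first_order(self):
        # K >> all concentrations: RP5 -> R*P/K**n (n=1 first-order expansion)
        R, P, K = 10.0, 5.0, 1e4
        bs = solve_bound_complex(R, P, K, 1)
        assert bs.rp5 == pytest.approx(R * P / K, rel=2e-3)


class TestRateLaw:
    def test_zero_free_rfc(self):
        assert predict_rate(0.0, 0.2, 10.0, 1) == 0.0
        assert predict_rate(0.0, 0.2, 10.0, 2) == 0.0

    @pytest.mark.parametrize("n", [1, 2])
    def test_half_saturation_at_K(self, n):
        assert predict_rate(17.3, 0.2, 17.3, n) == pytest.approx(0.1, abs=1e-15)

    def test_n1_equals_michaelis_menten_closed_form(self, rng):
        x = rng.uniform(0, 200, 1000)
        k_cat = rng.uniform(0.05, 0.5)
        K = rng.uniform(0.5, 100)
        assert np.array_equal(predict_rate(x, k_cat, K, 1),
                              k_cat * x / (x + K))

    def test_monotone_and_bounded(self, rng):
        x = np.sort(rng.uniform(0, 500, 100))
        for n in (1, 2):
            y = predict_rate(x, 0.2, 20.0, n)
            assert np.all(np.diff(y) > 0)
            assert np.all(y < 0.2)


class TestTitrationFit:
    def test_exact_recovery_noiseless_hyperbolic(self):
        series = gen_titration_series(0.2, 10.0, 1, rel_noise=0.0)
        fit = fit_titration(series, 50.0, 1)
        assert fit.k_cat == pytest.approx(0.2, rel=1e-6)
        assert fit.K == pytest.approx(10.0, rel=1e-6)
        assert fit.model_class == "hyperbolic"

    def test_depletion_ignored_biases_K_upward(self):
        """Fitting total RFC as if it were free inflates K; the correction
        restores exact recovery."""
        series = gen_titration_series(0.2, 10.0, 1, rel_noise=0.0)
        naive = fit_titration(series, 50.0, 1, depletion=False)
        corrected = fit_titration(series, 50.0, 1, depletion=True)
        assert naive.K > 10.0 * 1.5
        assert corrected.K == pytest.approx(10.0, rel=1e-6)

    def test_noisy_cooperative_recovery(self, rng):
        errs = []
        for _ in range(30):
            s = gen_titration_series(0.2, 28.0, 2, rel_noise=0.10, rng=rng)
            f = fit_titration(s, 50.0, 2, weighted=True)
            errs.append(abs(f.K - 28.0) / 28.0)
        assert np.median(errs) < 0.25

    def test_too_few_points_rejected(self):
        s = gen_titration_series(0.2, 10.0, 1, rfc_grid=(0, 30, 60, 120),
                                 rel_noise=0.0)
        with pytest.raises(FitError):
            fit_titration(s, 50.0, 1)


class TestModelSelection:
    def test_noiseless_hyperbolic_selected(self):
        s = gen_titration_series(0.2, 10.0, 1, rel_noise=0.0)
        fit = select_model(s, 50.0)
        assert fit.model_class == "hyperbolic" and fit.n == 1

    def test_noiseless_sigmoidal_selected(self):
        s = gen_titration_series(0.2, 28.0, 2, rel_noise=0.0)
        fit = select_model(s, 50.0)
        assert fit.model_class == "sigmoidal" and fit.n == 2
        assert fit.selection_stat["p"] < 0.05

    def test_detection_limit_flagged(self):
        s = gen_titration_series(0.2, 0.5, 1, rel_noise=0.0)
        fit = fit_titration(s, 50.0, 1)
        assert fit.at_detection_limit

    def test_aicc_criterion_available(self):
        s = gen_titration_series(0.2, 28.0, 2, rel_noise=0.0)
        fit = select_model(s, 50.0, criterion="aicc")
        assert fit.n == 2
        assert fit.selection_stat["criterion"] == "aicc"
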