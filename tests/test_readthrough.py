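"""RE quantitation, the competition model, and combination classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptckin.readthrough import (
    classify_combination,
    compute_re,
    delta_re,
    partition_probability,
)
from ptckin.simulate import (
    GeneratorConfig,
    calibrate_assoc_rate,
    gen_combination_panel,
    gen_readthrough_assay,
)


class TestComputeRE:
    def test_cognate_control_is_unity(self):
        assert compute_re(123.4, 123.4) == 1.0

    def test_zero_signal(self):
        assert compute_re(0.0, 50.0) == 0.0

    def test_bad_control_rejected(self):
        with pytest.raises(ValueError):
            compute_re(1.0, 0.0)

    @pytest.mark.parametrize("assay", ["cosedimentation", "fluorescence"])
    def test_basal_readthrough_calibration(self, assay, rng):
        """The generator is calibrated so the reference complex shows ~20%
        basal readthrough; compute_re must return it from simulated signals."""
        cfg = GeneratorConfig(seed=0)
        tbl = gen_readthrough_assay(0.2, 28.0, 2, assay=assay, replicates=12,
                                    cfg=cfg, rng=rng)
        res = [compute_re(r.signal, r.control_signal, assay)
               for r in tbl.itertuples()]
        assert np.mean(res) == pytest.approx(0.20, abs=0.02)

    def test_assay_formats_agree(self, rng):
        """Both assay formats applied to the same generative state give the
        same RE within simulated noise."""
        cfg = GeneratorConfig(seed=0)
        res = {}
        for assay in ("cosedimentation", "fluorescence"):
            tbl = gen_readthrough_assay(0.2, 10.0, 1, assay=assay,
                                        replicates=12, cfg=cfg, rng=rng)
            res[assay] = np.mean([compute_re(r.signal, r.control_signal, assay)
                                  for r in tbl.itertuples()])
        assert res["cosedimentation"] == pytest.approx(res["fluorescence"],
                                                       abs=0.03)


class TestDeltaRE:
    def test_arithmetic(self):
        d, _ = delta_re(0.35, 0.20)
        assert d == pytest.approx(15.0)

    def test_zero_for_equal(self):
        assert delta_re(0.4, 0.4)[0] == 0.0

    def test_sd_propagates_in_quadrature(self):
        _, sd = delta_re(0.3, 0.2, 0.03, 0.04)
        assert sd == pytest.approx(100 * math.hypot(0.03, 0.04))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_re(1.2, 0.2)


class TestPartition:
    def test_no_rfc_means_full_readthrough(self):
        p = partition_probability(0.2, 5.0, rfc_free=0.0, k_cat=0.2, K=10.0, n=1)
        assert p == 1.0

    def test_saturating_ataluren_limit(self):
        p = partition_probability(0.2, 5.0, rfc_free=50.0, k_cat=0.2, K=10.0,
                                  n=1, ataluren_mM=1e9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_bernoulli_competition_simulation(self, rng):
        """The closed-form partition equals the long-run fraction of a
        stochastic race between elongation and termination."""
        kwargs = dict(rfc_free=40.0, k_cat=0.25, K=15.0, n=1,
                      ataluren_mM=0.5, g418_factor=3.0)
        p = partition_probability(0.2, 5.0, **kwargs)
        n_trials = 100_000
        from ptckin.termination import predict_rate
        a = 5.0 * 3.0 * 0.2
        k_term = predict_rate(40.0, 0.25, 15.0 * (1 + 0.5 / 0.3), 1)
        t_rt = rng.exponential(1 / a, n_trials)
        t_term = rng.exponential(1 / k_term, n_trials)
        p_hat = np.mean(t_rt < t_term)
        mc_sd = math.sqrt(p * (1 - p) / n_trials)
        assert abs(p_hat - p) < 3 * mc_sd

    @settings(max_examples=50, deadline=None)
    @given(at=st.floats(0.0, 5.0), g=st.floats(1.0, 20.0),
           free=st.floats(0.1, 100.0))
    def test_monotonicities(self, at, g, free):
        base = dict(k_cat=0.2, K=10.0, n=1)
        p = partition_probability(0.2, 5.0, rfc_free=free, ataluren_mM=at,
                                  g418_factor=g, **base)
        assert p < partition_probability(0.2, 5.0, rfc_free=free,
                                         ataluren_mM=at + 1.0, g418_factor=g,
                                         **base)
        assert p < partition_probability(0.2, 5.0, rfc_free=free,
                                         ataluren_mM=at, g418_factor=g + 1.0,
                                         **base)
        assert p > partition_probability(0.2, 5.0, rfc_free=free + 10.0,
                                         ataluren_mM=at, g418_factor=g, **base)

    def test_invariant_under_joint_rescaling(self):
        """Scaling both competing fluxes by the same factor leaves p fixed."""
        p1 = partition_probability(0.2, 5.0, rfc_free=40.0, k_cat=0.2,
                                   K=10.0, n=1)
        p2 = partition_probability(0.2, 5.0 * 7.0, rfc_free=40.0,
                                   k_cat=0.2 * 7.0, K=10.0, n=1)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestCombinations:
    def test_exact_additive(self):
        res = classify_combination((0.10, 0.01), (0.25, 0.01), (0.30, 0.01),
                                   (0.45, 0.01))
        assert res.verdict == "additive"
        assert res.excess == pytest.approx(0.0, abs=1e-12)

    def test_synergistic_fixture(self):
        res = classify_combination((0.10, 0.02), (0.25, 0.02), (0.30, 0.02),
                                   (0.70, 0.02))
        assert res.verdict == "synergistic"
        assert res.z > 2

    def test_inactive_agent_gives_null(self):
        """A tight-binding complex where ataluren has no effect: no verdict
        beyond null even if the other agent works."""
        res = classify_combination((0.10, 0.02), (0.105, 0.02), (0.40, 0.02),
                                   (0.42, 0.02))
        assert res.verdict == "null"

    def test_sub_additive(self):
        res = classify_combination((0.10, 0.01), (0.30, 0.01), (0.30, 0.01),
                                   (0.55, 0.03))  # -0.05 excess = -1.5 sd? no
        # prediction 0.5; excess 0.05 over sd ~0.035 -> z ~1.4: additive
        assert res.verdict == "additive"
        res2 = classify_combination((0.10, 0.01), (0.30, 0.01), (0.30, 0.01),
                                    (0.30, 0.01))
        assert res2.verdict == "sub_additive"

    def test_missing_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_combination((0.1, 0.0), (0.2, 0.01), (0.2, 0.01),
                                 (0.3, 0.01))

    def test_label_recovery_on_synthetic_panel(self):
        """Generated combination panels are classified back to their labels
        with high accuracy at SD 0.02."""
        ok = tot = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            tbl = gen_combination_panel(9, sd=0.02, rng=rng)
            for r in tbl.itertuples():
                res = classify_combination(
                    (r.re_baseline, r.re_baseline_sd), (r.re_a, r.re_a_sd),
                    (r.re_b, r.re_b_sd), (r.re_combo, r.re_combo_sd))
                ok += res.verdict == r.true_verdict
                tot += 1
        assert ok / tot >= 0.90


def test_calibrated_assoc_rate_solves_target():
    cfg = GeneratorConfig(seed=0)
    from ptckin.simulate import true_partition
    a = calibrate_assoc_rate(0.2, 28.0, 2, cfg)
    p = true_partition(0.2, 28.0, 2, assoc_rate=a, cfg=cfg)
    assert p == pytest.approx(0.20, abs=1e-12)
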