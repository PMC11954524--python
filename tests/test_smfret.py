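"""Event extraction, dwell pooling, and exponential rate estimation."""

import numpy as np
import pytest

from ptckin.simulate import GeneratorConfig, gen_fret_trace
from ptckin.smfret import (
    DwellSet,
    FretTrace,
    estimate_rates,
    extract_events,
    fret_efficiency,
)


def make_step_trace(arrival=200, cy3_loss=500, alex_loss=700, n=1200,
                    E=0.25, high=100.0, noise=0.0, rng=None):
    donor = np.zeros(n)
    afret = np.zeros(n)
    adirect = np.zeros(n)
    adirect[arrival:alex_loss] = high
    fret_end = min(cy3_loss, alex_loss)
    donor[:cy3_loss] = high
    donor[arrival:fret_end] = high * (1 - E)
    afret[arrival:fret_end] = high * E
    if noise > 0:
        donor = donor + rng.normal(0, noise, n)
        afret = afret + rng.normal(0, noise * E, n)
        adirect = adirect + rng.normal(0, noise, n)
    return FretTrace(frame_time=0.1, donor=donor, acceptor_fret=afret,
                     acceptor_direct=adirect, injection_frame=100)


class TestExtractEvents:
    def test_noiseless_step_trace_exact(self):
        ev = extract_events(make_step_trace())
        assert ev.arrival_frame == 200
        assert ev.fret_start_frame == 200
        assert ev.cy3_loss_frame == 500
        assert ev.alex_loss_frame == 700
        assert not ev.cy3_censored and not ev.alex_censored

    def test_no_acceptor_appearance_is_empty(self, rng):
        n = 1200
        tr = FretTrace(frame_time=0.1, donor=100 + rng.normal(0, 5, n),
                       acceptor_fret=rng.normal(0, 5, n),
                       acceptor_direct=rng.normal(0, 5, n),
                       injection_frame=100)
        ev = extract_events(tr)
        assert ev.empty

    def test_censored_losses_flagged(self):
        # bound state persists to the end of the recording
        ev = extract_events(make_step_trace(cy3_loss=1200, alex_loss=1200))
        assert ev.alex_censored and ev.cy3_censored

    def test_event_ordering_invariants_on_simulated_traces(self):
        cfg = GeneratorConfig(seed=7, snr=5.0)
        rng = cfg.rng()
        for _ in range(100):
            tr = gen_fret_trace(cfg, rng)
            ev = extract_events(tr)
            if ev.empty:
                continue
            assert ev.arrival_frame >= tr.injection_frame
            if ev.fret_start_frame is not None:
                assert ev.fret_start_frame >= ev.arrival_frame
                assert ev.cy3_loss_frame >= ev.fret_start_frame
            assert ev.alex_loss_frame >= ev.arrival_frame

    def test_detection_accuracy_at_snr5(self):
        """At SNR 5 the large majority of events land within 2 frames."""
        cfg = GeneratorConfig(seed=3, snr=5.0)
        rng = cfg.rng()
        hits = tot = 0
        for _ in range(150):
            tr, truth = gen_fret_trace(cfg, rng, return_truth=True)
            if truth["arrival_frame"] is None:
                continue
            ev = extract_events(tr)
            for evf, tf in ((ev.arrival_frame, truth["arrival_frame"]),
                            (ev.cy3_loss_frame, truth["cy3_loss_frame"]),
                            (ev.alex_loss_frame, truth["alex_loss_frame"])):
                if tf >= tr.n_frames:
                    continue
                tot += 1
                hits += evf is not None and abs(evf - tf) <= 2
        assert hits / tot >= 0.93


class TestRates:
    def test_exponential_rate_recovery(self, rng):
        ds = DwellSet(arrival_waits=list(rng.exponential(10.0, 2000)),
                      tRNA_bound_durations=list(rng.exponential(8.0, 2000)),
                      erf1_bound_durations=list(rng.exponential(12.0, 2000)))
        ds = estimate_rates(ds, seed=1)
        assert ds.k_arrival_app == pytest.approx(0.1, rel=0.05)
        assert ds.k_dis_tRNA_app == pytest.approx(1 / 8.0, rel=0.05)
        assert ds.k_dis_eRF1_app == pytest.approx(1 / 12.0, rel=0.05)
        lo, hi = ds.ci["k_arrival_app"]
        assert lo < 0.1 < hi

    def test_too_few_dwells_rejected(self, rng):
        ds = DwellSet(arrival_waits=list(rng.exponential(10.0, 5)),
                      tRNA_bound_durations=list(rng.exponential(8.0, 100)),
                      erf1_bound_durations=list(rng.exponential(12.0, 100)))
        with pytest.raises(ValueError, match="k_arrival_app"):
            estimate_rates(ds)

    def test_all_censored_input_rejected(self):
        ds = DwellSet()  # nothing uncensored collected
        with pytest.raises(ValueError):
            estimate_rates(ds)

    def test_estimator_consistency(self, rng):
        """Relative error shrinks as the dwell count grows."""
        errs = {}
        for n in (50, 500, 5000):
            reps = [abs(1 / np.mean(rng.exponential(10.0, n)) - 0.1) / 0.1
                    for _ in range(40)]
            errs[n] = np.mean(reps)
        assert errs[5000] < errs[500] < errs[50]

    def test_fourfold_rate_difference_resolved(self, rng):
        """Two conditions with a 4x generative rate ratio give an estimated
        ratio in [3, 5]."""
        slow = 1 / np.mean(rng.exponential(20.0, 400))
        fast = 1 / np.mean(rng.exponential(5.0, 400))
        assert 3.0 < fast / slow < 5.0

    def test_twofold_band_maps_to_2p5fold_band(self, rng):
        """Generative rates within a 2-fold band estimate within 2.5-fold."""
        rates = np.linspace(0.06, 0.12, 13)  # two-fold range
        est = [1 / np.mean(rng.exponential(1 / r, 300)) for r in rates]
        assert max(est) / min(est) < 2.5


class TestFretEfficiency:
    def test_equal_intensities(self):
        assert fret_efficiency(50.0, 50.0) == 0.5

    def test_zero_acceptor(self):
        assert fret_efficiency(80.0, 0.0) == 0.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 0.0)

    def test_fixture_efficiency_recovered(self):
        cfg = GeneratorConfig(seed=11, snr=5.0, E_true=0.25)
        rng = cfg.rng()
        ds = DwellSet.from_traces(gen_fret_trace(cfg, rng) for _ in range(150))
        assert ds.E == pytest.approx(0.25, abs=0.02)
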