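"""PSTH construction, onset alignment, adaptation/recovery fits, vector
strength and rate-level metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochsyn import (PSTHData, SpikeTrainSet, align_onsets, build_psth,
                     detect_onset, fit_adaptation, fit_recovery,
                     forward_masking_ratio, generate_psth_curve,
                     peak_and_adapted, rate_level_metrics,
                     synchronization_index)


def psth_from_rates(rates, bin_ms=2.0, n_trials=200, onset=None):
    bw = bin_ms * 1e-3
    edges = np.arange(len(rates) + 1) * bw
    return PSTHData(bin_width=bw, edges=edges,
                    rate=np.asarray(rates, float),
                    n_trials=n_trials, onset=onset)


class TestBuildPsth:
    def test_rate_normalization(self):
        # 200 trials, one spike each in the same 2 ms bin -> 2.5 Hz... per
        # spike: 1/(200*0.002) Hz; 200 spikes -> 500 Hz
        trials = [np.array([0.0101])] * 200
        psth = build_psth(SpikeTrainSet(trials, duration=0.1))
        k = int(0.0101 / 0.002)
        assert psth.rate[k] == pytest.approx(200 / (200 * 0.002))
        assert psth.rate.sum() == pytest.approx(psth.rate[k])

    def test_single_spike_rate(self):
        trials = [np.array([0.0101])] + [np.empty(0)] * 199
        psth = build_psth(SpikeTrainSet(trials, duration=0.1))
        assert psth.rate.max() == pytest.approx(1 / (200 * 0.002))

    def test_empty_trains_give_zero_psth(self):
        psth = build_psth(SpikeTrainSet([np.empty(0)] * 5, duration=0.1))
        assert np.all(psth.rate == 0.0)

    def test_duplicating_trials_preserves_rates(self):
        rng = np.random.default_rng(1)
        trials = [np.sort(rng.uniform(0, 0.1, 8)) for _ in range(20)]
        p1 = build_psth(SpikeTrainSet(trials, duration=0.1))
        p2 = build_psth(SpikeTrainSet(trials * 2, duration=0.1))
        assert np.allclose(p1.rate, p2.rate)

    def test_merged_sets_average_by_trial_count(self):
        rng = np.random.default_rng(2)
        a = [np.sort(rng.uniform(0, 0.1, 5)) for _ in range(10)]
        b = [np.sort(rng.uniform(0, 0.1, 5)) for _ in range(30)]
        pa = build_psth(SpikeTrainSet(a, duration=0.1))
        pb = build_psth(SpikeTrainSet(b, duration=0.1))
        pm = build_psth(SpikeTrainSet(a + b, duration=0.1))
        expect = (10 * pa.rate + 30 * pb.rate) / 40
        assert np.allclose(pm.rate, expect)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([], duration=0.1)


class TestOnsetAlignment:
    def make_step_unit(self, shift_bins=0, spont=0.0, n_trials=200):
        rates = np.full(50, spont)
        rates[15 + shift_bins:] = 400.0
        return psth_from_rates(rates, n_trials=n_trials)

    def test_step_onset_with_silent_baseline(self):
        psth = self.make_step_unit()
        assert detect_onset(psth, (0.0, 0.03)) == 15

    def test_alignment_recovers_known_shift(self):
        a, b = self.make_step_unit(0), self.make_step_unit(3)  # 6 ms apart
        avg, onsets = align_onsets([a, b], (0.0, 0.02))
        assert onsets[1] - onsets[0] == pytest.approx(6e-3)
        # after alignment the average equals the unshifted step
        assert np.allclose(avg.rate[:30], a.rate[:30])

    def test_average_of_identical_copies_is_identity(self):
        p = self.make_step_unit()
        avg, _ = align_onsets([p, p, p], (0.0, 0.02))
        assert np.allclose(avg.rate, p.rate[:len(avg.rate)])

    def test_unalignable_unit_excluded(self):
        flat = psth_from_rates(np.full(50, 100.0))
        step = self.make_step_unit(spont=20.0)
        avg, onsets = align_onsets([step, flat], (0.0, 0.02))
        assert onsets[1] is None
        assert np.allclose(avg.rate, step.rate[:len(avg.rate)])

    def test_shift_equivariance(self):
        base = self.make_step_unit(0)
        shifted = self.make_step_unit(4)
        o1 = detect_onset(base, (0.0, 0.02))
        o2 = detect_onset(shifted, (0.0, 0.02))
        assert o2 - o1 == 4


class TestPeakAndAdapted:
    def test_flat_psth(self):
        psth = psth_from_rates(np.full(40, 100.0))
        peak, adapted = peak_and_adapted(psth, onset=0.0)
        assert peak == adapted == pytest.approx(100.0)

    def test_known_peak_bin(self):
        rates = np.zeros(40)
        rates[3] = 700.0  # bin center 7 ms: inside the 3-11 ms window
        rates[20] = 50.0  # adapted window 35-45 ms
        psth = psth_from_rates(rates)
        peak, adapted = peak_and_adapted(psth, onset=0.0)
        assert peak == pytest.approx(700.0)
        assert adapted == pytest.approx(50.0 / 5)

    def test_window_out_of_range(self):
        psth = psth_from_rates(np.full(5, 10.0))
        with pytest.raises(ValueError):
            peak_and_adapted(psth, onset=0.0)


class TestAdaptationFits:
    def test_double_fit_recovers_generating_taus(self, table1_wt):
        psth = generate_psth_curve(**table1_wt)
        res = fit_adaptation(psth, onset=0.0, kind="double")
        assert res.tau_fast == pytest.approx(table1_wt["tau_fast"],
                                             rel=1e-4)
        assert res.tau_slow == pytest.approx(table1_wt["tau_slow"],
                                             rel=1e-4)
        assert res.tau_fast <= res.tau_slow

    def test_single_fit_self_consistency(self):
        t = (np.arange(25) + 0.5) * 2.0
        rates = 30.0 + 300.0 * np.exp(-t / 8.0)
        res = fit_adaptation(psth_from_rates(rates), onset=0.0,
                             kind="single")
        assert res.tau == pytest.approx(8.0, rel=1e-6)
        assert res.offset == pytest.approx(30.0, rel=1e-4)

    def test_constant_input_gives_zero_amplitude(self):
        res = fit_adaptation(psth_from_rates(np.full(25, 120.0)),
                             onset=0.0, kind="single")
        assert abs(res.amplitude) < 1e-3
        assert res.offset == pytest.approx(120.0, abs=1e-3)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation(psth_from_rates(np.ones(5)), onset=0.0)


class TestForwardMaskingRatio:
    def trains(self, n_masker, n_probe, n_trials=30):
        spikes = np.concatenate([
            np.linspace(0.001, 0.009, n_masker),
            0.2 + np.linspace(0.001, 0.009, n_probe)])
        return SpikeTrainSet([np.sort(spikes)] * n_trials, duration=0.5)

    def test_identical_responses_unity(self):
        s = self.trains(6, 6)
        assert forward_masking_ratio(s, 0.0, 0.2) == pytest.approx(1.0)

    def test_half_response(self):
        s = self.trains(6, 3)
        assert forward_masking_ratio(s, 0.0, 0.2) == pytest.approx(0.5)

    def test_zero_masker_flagged(self):
        s = self.trains(0, 3)
        with pytest.raises(ValueError):
            forward_masking_ratio(s, 0.0, 0.2)

    def test_few_trials_warn(self):
        s = self.trains(6, 3, n_trials=10)
        with pytest.warns(UserWarning):
            forward_masking_ratio(s, 0.0, 0.2)


class TestRecoveryFit:
    def test_round_trip(self):
        gaps = np.array([4e-3, 16e-3, 64e-3, 256e-3])
        ratios = 1.0 - 0.8 * np.exp(-gaps * 1e3 / 50.0)
        tau, a, ok = fit_recovery(gaps, ratios)
        assert ok
        assert tau == pytest.approx(50.0, rel=1e-6)
        assert a == pytest.approx(0.8, rel=1e-6)

    def test_flat_ratios_flagged(self):
        tau, a, ok = fit_recovery([4e-3, 16e-3, 64e-3], [1.0, 1.0, 1.0])
        assert not ok

    def test_noisy_population_recovery(self):
        rng = np.random.default_rng(42)
        gaps = np.array([4e-3, 16e-3, 64e-3, 256e-3])
        taus = []
        for _ in range(25):
            ratios = 1 - 0.8 * np.exp(-gaps * 1e3 / 50.0) \
                + rng.normal(0, 0.05, 4)
            tau, _, ok = fit_recovery(gaps, np.clip(ratios, 0, 1.2))
            if ok:
                taus.append(tau)
        assert abs(np.mean(taus) - 50.0) / 50.0 < 0.15


class TestSynchronizationIndex:
    def test_perfect_locking(self):
        t = np.arange(20) * 2e-3  # all at phase 0 of a 2 ms cycle
        si, stat, valid = synchronization_index(t, 2e-3)
        assert si == pytest.approx(1.0)
        assert valid

    def test_antiphase_pairs_cancel(self):
        t = np.array([0.0, 1e-3] * 10)  # phases 0 and pi
        si, _, valid = synchronization_index(t, 2e-3)
        assert si == pytest.approx(0.0, abs=1e-12)
        assert not valid

    def test_uniform_phases_not_significant(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 1.0, 1000)
        si, stat, valid = synchronization_index(t, 2e-3)
        assert si < 3.0 / np.sqrt(1000)
        assert not valid

    def test_empty_input_invalid(self):
        si, stat, valid = synchronization_index([], 2e-3)
        assert not valid

    @given(shift=st.integers(0, 20), n=st.integers(16, 60))
    @settings(max_examples=30, deadline=None)
    def test_invariance_to_whole_period_shifts(self, shift, n):
        rng = np.random.default_rng(n)
        t = rng.uniform(0, 10e-3, n)
        period = 2e-3
        si1, _, _ = synchronization_index(t, period)
        si2, _, _ = synchronization_index(t + shift * period, period)
        assert si1 == pytest.approx(si2, abs=1e-9)


class TestRateLevel:
    def test_logistic_dynamic_range_closed_form(self):
        L = np.arange(0, 80, 5.0)
        rates = 10 + 190 / (1 + np.exp(-(L - 40) / 5.0))
        m = rate_level_metrics(L, rates)
        assert not m["flagged"]
        assert m["dynamic_range_db"] == pytest.approx(2 * 5 * np.log(9),
                                                      rel=1e-4)

    def test_flat_rates_flagged(self):
        m = rate_level_metrics(np.arange(0, 40, 5.0), np.full(8, 50.0))
        assert m["flagged"]
        assert np.isnan(m["dynamic_range_db"])

    def test_ramp_steepness(self):
        L = np.arange(0, 40, 5.0)
        rates = 20.0 * np.arange(8)
        m = rate_level_metrics(L, rates)
        assert m["max_steepness"] == pytest.approx(20.0)
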