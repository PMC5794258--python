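"""Release-site model: rate mapping, occupancy ODE, refractoriness DDE,
steady states and periodic protocol simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochsyn import (Envelope, KineticParams, RefractoryParams,
                     epsc_rate, integrate_occupancy,
                     integrate_refractoriness, rates_at, simulate_protocol,
                     steady_state_ap_rate, steady_state_epsc_rate,
                     steady_state_occupancy)
from cochsyn.protocols import forward_masking_protocol

DT = 5e-5


def flat_envelope(level: float, duration: float = 0.5) -> Envelope:
    n = int(round(duration / DT))
    return Envelope(np.arange(n + 1) * DT, np.full(n + 1, level), duration)


class TestRateMapping:
    def test_silence_endpoint(self, wt_fm_params):
        env = flat_envelope(0.0)
        kr, kf = rates_at(wt_fm_params, env, 0.1)
        assert kr == pytest.approx(13.3)
        assert kf == pytest.approx(0.6)

    def test_saturation_endpoint(self, wt_fm_params):
        env = flat_envelope(1.0)
        kr, kf = rates_at(wt_fm_params, env, 0.1)
        assert kr == pytest.approx(29.5)
        assert kf == pytest.approx(32.2)

    def test_linear_midpoint(self, wt_fm_params):
        env = flat_envelope(0.5)
        kr, _ = rates_at(wt_fm_params, env, 0.1)
        assert kr == pytest.approx(21.4)

    def test_outside_grid_raises(self, wt_fm_params):
        env = flat_envelope(0.0, duration=0.1)
        with pytest.raises(ValueError):
            rates_at(wt_fm_params, env, 0.2)


class TestSteadyStates:
    def test_no_fusion_fills_pool(self):
        assert steady_state_occupancy(13.3, 0.0, 8.0) == pytest.approx(8.0)

    def test_no_refill_empties_pool(self):
        assert steady_state_occupancy(0.0, 0.6, 8.0) == pytest.approx(0.0)

    def test_spontaneous_occupancy(self):
        assert steady_state_occupancy(13.3, 0.6, 8.0) == pytest.approx(
            7.655, abs=5e-4)

    def test_both_rates_zero_raises(self):
        with pytest.raises(ValueError):
            steady_state_occupancy(0.0, 0.0, 8.0)

    def test_spontaneous_epsc_rate(self, wt_fm_params):
        assert steady_state_epsc_rate(wt_fm_params, "spont") == \
            pytest.approx(4.593, abs=5e-4)

    def test_stimulated_epsc_rate(self, wt_fm_params):
        assert steady_state_epsc_rate(wt_fm_params, "stim") == \
            pytest.approx(123.2, abs=0.05)

    def test_ap_rate_without_refractoriness_equals_epsc_rate(
            self, wt_fm_params):
        none = RefractoryParams(0.0, 0.0)
        for cond in ("spont", "stim"):
            assert steady_state_ap_rate(wt_fm_params, none, cond) == \
                pytest.approx(steady_state_epsc_rate(wt_fm_params, cond))

    def test_spontaneous_ap_rate(self, wt_fm_params, refrac):
        assert steady_state_ap_rate(wt_fm_params, refrac, "spont") == \
            pytest.approx(4.568, abs=5e-4)

    def test_refractoriness_always_reduces_rate(self, wt_fm_params, refrac):
        for cond in ("spont", "stim"):
            assert steady_state_ap_rate(wt_fm_params, refrac, cond) < \
                steady_state_epsc_rate(wt_fm_params, cond)

    @given(kr=st.floats(0.5, 100), extra=st.floats(0.1, 50),
           n1=st.floats(1, 30), dn=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_refill_and_capacity(self, kr, extra, n1, dn):
        refrac = RefractoryParams(0.6e-3, 0.6e-3)

        def ap(krefill, n):
            p = KineticParams(n, krefill, krefill, 0.6, 0.6, f=1.0)
            return steady_state_ap_rate(p, refrac, "spont")

        assert ap(kr + extra, n1) >= ap(kr, n1) - 1e-12
        assert ap(kr, n1 + dn) >= ap(kr, n1) - 1e-12


class TestEpscRate:
    def test_empty_pool_is_silent(self, wt_fm_params):
        assert epsc_rate(wt_fm_params, 0.6, 0.0) == 0.0

    def test_spontaneous_value(self, wt_fm_params):
        assert epsc_rate(wt_fm_params, 0.6, 7.655) == pytest.approx(
            4.593, abs=1e-3)

    def test_linear_in_f(self):
        half = KineticParams(8, 13.3, 29.5, 0.6, 32.2, f=0.5)
        full = KineticParams(8, 13.3, 29.5, 0.6, 32.2, f=1.0)
        assert epsc_rate(half, 0.6, 7.0) == pytest.approx(
            0.5 * epsc_rate(full, 0.6, 7.0))


class TestOccupancyIntegration:
    def test_fixed_point_stays_constant(self, wt_fm_params):
        env = flat_envelope(0.0)
        n_ss = steady_state_occupancy(13.3, 0.6, 8.0)
        n = integrate_occupancy(wt_fm_params, env, n_ss)
        assert np.allclose(n, n_ss, rtol=1e-9)

    def test_relaxation_matches_closed_form(self, wt_fm_params):
        # dN/dt linear ODE: N(t) = N_ss (1 - exp(-(kf+kr) t)) from N(0)=0
        env = flat_envelope(0.0)
        n = integrate_occupancy(wt_fm_params, env, 0.0)
        n_ss = 13.3 / 13.9 * 8.0
        oracle = n_ss * (1.0 - np.exp(-13.9 * env.t))
        assert np.max(np.abs(n - oracle)) / n_ss < 1e-3

    def test_pure_depletion_decays_monotonically(self):
        p = KineticParams(8, 0.0, 0.0, 0.6, 32.2, f=1.0)
        env = flat_envelope(0.5)
        n = integrate_occupancy(p, env, 5.0)
        assert np.all(np.diff(n) <= 1e-12)
        assert n[-1] < 0.01 * n[0]

    def test_unstable_step_refused(self, wt_fm_params):
        env = flat_envelope(0.0)
        with pytest.raises(ValueError):
            integrate_occupancy(wt_fm_params, env, 0.0, dt=0.1)

    def test_bad_initial_occupancy_refused(self, wt_fm_params):
        with pytest.raises(ValueError):
            integrate_occupancy(wt_fm_params, flat_envelope(0.0), 9.0)


class TestRefractorinessDDE:
    def test_recovery_to_full_availability_without_drive(self, refrac):
        E = np.zeros(8001)
        fa, fr, fb, ap = integrate_refractoriness(
            E, refrac, DT, init=(0.5, 0.5, 0.0))
        assert np.all(np.diff(fa) >= -1e-12)
        assert fa[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(ap == 0.0)

    def test_no_refractoriness_limit_is_identity(self):
        E = np.full(2001, 50.0)
        none = RefractoryParams(0.0, 0.0)
        _, _, _, ap = integrate_refractoriness(E, none, DT)
        assert np.allclose(ap, E)

    def test_constant_drive_reaches_closed_form(self, refrac):
        E = np.full(40001, 123.2)
        _, _, _, ap = integrate_refractoriness(
            E, refrac, DT, init=(1.0, 0.0, 0.0),
            history=np.zeros(13))
        expect = 123.2 / (1.0 + 123.2 * 1.2e-3)
        assert ap[-1] == pytest.approx(expect, rel=5e-3)

    def test_steady_state_initialization_is_stationary(self, refrac):
        E = np.full(2001, 80.0)
        fa, fr, fb, ap = integrate_refractoriness(E, refrac, DT)
        assert np.ptp(ap) < 1e-8 * ap[0]

    def test_conservation_of_state_fractions(self, refrac):
        rng = np.random.default_rng(0)
        E = 50.0 + 30.0 * np.sin(np.linspace(0, 20, 5001)) ** 2
        fa, fr, fb, _ = integrate_refractoriness(E, refrac, DT)
        assert np.max(np.abs(fa + fr + fb - 1.0)) < 1e-6

    def test_negative_drive_rejected(self, refrac):
        with pytest.raises(ValueError):
            integrate_refractoriness(np.array([-1.0, 0.0]), refrac, DT)

    def test_instantaneous_relative_recovery(self):
        r = RefractoryParams(t_abs=0.6e-3, tau_rel=0.0)
        E = np.full(20001, 100.0)
        fa, fr, fb, ap = integrate_refractoriness(E, r, DT)
        assert np.all(fr == 0.0)
        assert ap[-1] == pytest.approx(100 / (1 + 100 * 0.6e-3), rel=5e-3)


class TestProtocolSimulation:
    def test_silence_gives_spontaneous_steady_state(self, wt_fm_params,
                                                    refrac):
        env = flat_envelope(0.0, duration=0.2)
        traj = simulate_protocol(wt_fm_params, refrac, env)
        expect = steady_state_ap_rate(wt_fm_params, refrac, "spont")
        assert np.allclose(traj.ap_rate, expect, rtol=1e-4)

    def test_probe_occupancy_recovers_with_gap(self, wt_fm_params, refrac):
        occ = []
        for gap in (4e-3, 16e-3, 64e-3, 256e-3):
            traj = simulate_protocol(wt_fm_params, refrac,
                                     forward_masking_protocol(gap))
            i = int(round((0.1 + gap) / DT))
            occ.append(traj.n_filled[i])
        assert np.all(np.diff(occ) > 0)

    def test_converged_cycle_is_invariant(self, wt_fm_params, refrac):
        proto = forward_masking_protocol(16e-3)
        traj = simulate_protocol(wt_fm_params, refrac, proto)
        # one extra cycle starting from the converged start state
        traj2 = simulate_protocol(wt_fm_params, refrac, proto,
                                  max_cycles=traj.n_cycles + 1)
        assert np.max(np.abs(traj2.ap_rate - traj.ap_rate)) < \
            1e-4 * np.max(traj.ap_rate)

    def test_trajectory_invariants(self, wt_fm_params, refrac):
        traj = simulate_protocol(wt_fm_params, refrac,
                                 forward_masking_protocol(64e-3))
        assert np.all(traj.n_filled >= 0)
        assert np.all(traj.n_filled <= wt_fm_params.n_slots + 1e-9)
        assert np.max(np.abs(traj.f_avail + traj.f_relref +
                             traj.f_absref - 1.0)) < 1e-6
        assert np.all(traj.ap_rate >= -1e-12)
        assert np.all(traj.ap_rate <= traj.epsc_rate + 1e-9)

    def test_step_halving_convergence(self, wt_fm_params, refrac):
        proto = forward_masking_protocol(16e-3)
        t1 = simulate_protocol(wt_fm_params, refrac, proto, dt=5e-5)
        t2 = simulate_protocol(wt_fm_params, refrac, proto, dt=2.5e-5)
        diff = np.max(np.abs(t2.ap_rate[::2] - t1.ap_rate))
        assert diff < 1e-3 * np.max(t1.ap_rate)
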