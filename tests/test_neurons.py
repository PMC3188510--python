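"""EIF membrane dynamics: spike nonlinearity, resting point, post-spike
relaxation and the cutoff-and-extrapolate spike-time scheme."""
import math

import numpy as np
import pytest

from hypercol.config import (ConfigError, NeuronParams, SOFT_REFRACTORY_DEFAULT,
                             HARD_REFRACTORY_DEFAULT, default_spec)
from hypercol.neurons import (NeuronState, integrate_single_neuron,
                              membrane_rhs, post_spike_update,
                              resting_potential, spike_nonlinearity,
                              relax_soft_state, time_to_divergence)

EXC = default_spec().neurons["E"]


class TestSpikeNonlinearity:
    def test_at_threshold_equals_slope_factor(self):
        assert spike_nonlinearity(-45.2, -45.2, 1.2) == pytest.approx(1.2)

    def test_one_slope_above_threshold(self):
        assert spike_nonlinearity(-45.2 + 1.2, -45.2, 1.2) == pytest.approx(
            1.2 * math.e, rel=1e-12)

    def test_vanishes_far_below(self):
        assert spike_nonlinearity(-45.2 - 50 * 1.2, -45.2, 1.2) < 1e-20

    def test_matches_numerical_derivative_of_trajectory(self):
        """Psi inferred from a finely integrated free trajectory (dV/dt =
        (E_L - V + Psi)/tau) matches the closed form."""
        v0 = EXC.v_threshold + 0.5 * EXC.delta_t
        dt = 1e-4
        _, v, _ = integrate_single_neuron(EXC, None, duration=0.01, dt=dt, v0=v0)
        dvdt = (v[2] - v[0]) / (2 * dt)
        psi_implied = dvdt * EXC.tau_m - (EXC.e_leak - v[1])
        assert psi_implied == pytest.approx(
            float(spike_nonlinearity(v[1], EXC.v_threshold, EXC.delta_t)), rel=2e-2)


class TestMembraneRhs:
    def test_near_rest_drift_is_negligible(self):
        st = NeuronState(EXC.e_leak, 1 / EXC.tau_m, EXC.v_threshold, EXC.delta_t)
        drift = membrane_rhs(st, 0.0, EXC)
        expected = 1.2 * math.exp(-12.6 / 1.2) / 23.3
        assert drift == pytest.approx(expected, rel=1e-9)
        assert drift < 1e-5

    def test_current_to_capacitance_arithmetic(self):
        st = NeuronState(EXC.e_leak, 1 / EXC.tau_m, EXC.v_threshold, EXC.delta_t)
        base = membrane_rhs(st, 0.0, EXC)
        assert membrane_rhs(st, 0.26, EXC) - base == pytest.approx(1.0)

    def test_larger_slope_factor_weakens_suprathreshold_drive(self):
        # holds where the exponent exceeds one for both slope factors,
        # i.e. V above V_T + 2*delta_t for the doubled value
        for v in np.linspace(EXC.v_threshold + 3.0, EXC.v_threshold + 8.0, 13):
            lo = NeuronState(v, 1 / EXC.tau_m, EXC.v_threshold, EXC.delta_t)
            hi = NeuronState(v, 1 / EXC.tau_m, EXC.v_threshold, 2 * EXC.delta_t)
            assert membrane_rhs(hi, 0.0, EXC) < membrane_rhs(lo, 0.0, EXC)


class TestRestingPotential:
    def test_matches_bisection_oracle(self):
        f = lambda v: EXC.e_leak - v + float(
            spike_nonlinearity(v, EXC.v_threshold, EXC.delta_t))
        lo, hi = -80.0, EXC.v_threshold
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert resting_potential(EXC) == pytest.approx(0.5 * (lo + hi), abs=1e-6)
        assert resting_potential(EXC) == pytest.approx(-57.8, abs=1e-3)

    def test_small_slope_factor_limit_is_leak(self):
        p = NeuronParams("E", 23.3, 0.26, delta_t=1e-4)
        assert resting_potential(p) == pytest.approx(p.e_leak, abs=1e-6)

    def test_leak_above_threshold_has_no_rest(self):
        p = NeuronParams("E", 23.3, 0.26, e_leak=-40.0)
        with pytest.raises(ConfigError):
            resting_potential(p)


class TestPostSpikeUpdate:
    def test_threshold_jump_is_sum_of_components(self):
        st = NeuronState.at_rest(EXC)
        new = post_spike_update(st, SOFT_REFRACTORY_DEFAULT, EXC, spike_time=100.0)
        assert new.v_threshold - EXC.v_threshold == pytest.approx(22.9 + 13.5)
        assert new.delta_t - EXC.delta_t == pytest.approx(10.0)
        assert new.inv_tau_m - 1 / EXC.tau_m == pytest.approx(0.14)
        assert new.v == EXC.reset

    def test_relaxation_within_one_percent_after_ten_time_constants(self):
        st = post_spike_update(NeuronState.at_rest(EXC), SOFT_REFRACTORY_DEFAULT,
                               EXC, 0.0)
        st = relax_soft_state(st, SOFT_REFRACTORY_DEFAULT, EXC, dt=762.0)
        assert abs(st.v_threshold - EXC.v_threshold) < 0.01 * 36.4
        assert abs(st.delta_t - EXC.delta_t) < 0.01 * 10.0
        assert abs(st.inv_tau_m - 1 / EXC.tau_m) < 0.01 * 0.14

    def test_offsets_reset_not_summed(self):
        st = post_spike_update(NeuronState.at_rest(EXC), SOFT_REFRACTORY_DEFAULT,
                               EXC, 0.0)
        again = post_spike_update(st, SOFT_REFRACTORY_DEFAULT, EXC, 1.0)
        assert again.v_threshold == pytest.approx(EXC.v_threshold + 36.4)

    def test_hard_mode_suspends_integration(self):
        inh = default_spec().neurons["I"]
        # constant suprathreshold current: ISI can never be shorter than the
        # refractory period
        _, _, spikes = integrate_single_neuron(
            inh, HARD_REFRACTORY_DEFAULT, duration=300.0, dt=0.05,
            current=lambda t: 0.6)
        isi = np.diff(spikes)
        assert spikes.size > 5
        assert np.all(isi >= HARD_REFRACTORY_DEFAULT.refractory_period - 1e-9)


class TestTimeToDivergence:
    def test_formula_anchor_at_threshold(self):
        assert time_to_divergence(-45.2, -45.2, 1.2, 23.3) == pytest.approx(23.3)

    def test_closed_form_vs_fine_integration(self):
        """Remaining divergence time from the cutoff matches brute-force
        sub-microsecond integration of the full membrane equation."""
        v0 = EXC.v_threshold + 10 * EXC.delta_t
        approx = float(time_to_divergence(v0, EXC.v_threshold, EXC.delta_t,
                                          EXC.tau_m))
        assert approx == pytest.approx(23.3 * math.exp(-10), rel=1e-12)
        # brute force: integrate with tiny steps until blow-up
        v, t, h = v0, 0.0, 1e-6
        while v < v0 + 2000 and t < 1.0:
            v += h * (EXC.e_leak - v + EXC.delta_t
                      * math.exp(min((v - EXC.v_threshold) / EXC.delta_t, 50))) / EXC.tau_m
            t += h
        assert approx == pytest.approx(t, rel=0.02)

    def test_monotone_decreasing_in_voltage(self):
        v = np.linspace(-40, -12, 50)  # below the overflow-guard cap
        out = time_to_divergence(v, -45.2, 1.2, 23.3)
        assert np.all(np.diff(out) < 0)


class TestIntegrationScheme:
    def test_free_neuron_converges_to_rest_from_any_subthreshold_start(self):
        rest = resting_potential(EXC)
        for v0 in np.linspace(-80.0, EXC.v_threshold - 1.0, 7):
            _, v, spikes = integrate_single_neuron(EXC, None, duration=500.0,
                                                   dt=0.2, v0=v0)
            assert spikes.size == 0
            assert v[-1] == pytest.approx(rest, abs=1e-3)

    def test_spike_times_match_fine_reference(self):
        """Cutoff + extrapolation at dt = 0.2 ms: spike times within 0.02 ms
        and ISIs within 0.05 ms of a 1000x finer reference integration."""
        cur = lambda t: 0.35  # suprathreshold, nA
        _, _, coarse = integrate_single_neuron(EXC, SOFT_REFRACTORY_DEFAULT,
                                               duration=400.0, dt=0.2, current=cur)
        _, _, fine = integrate_single_neuron(EXC, SOFT_REFRACTORY_DEFAULT,
                                             duration=400.0, dt=0.0002, current=cur)
        n = min(coarse.size, fine.size)
        assert n >= 3
        # per-event timing error of the scheme (first threshold passage) and
        # per-cycle error in the steady firing; the cumulative drift over many
        # cycles is ordinary truncation error, not part of the spike scheme
        assert abs(coarse[0] - fine[0]) < 0.02
        assert np.max(np.abs(np.diff(coarse[:n]) - np.diff(fine[:n]))) < 0.05

    def test_excitatory_spikes_never_closer_than_one_millisecond(self, mini_run_high):
        res = mini_run_high
        exc = np.concatenate([res.population_indices("upper_E"),
                              res.population_indices("lower_E")])
        mask = np.isin(res.spike_ids, exc)
        ids, times = res.spike_ids[mask], res.spike_times[mask]
        for nid in np.unique(ids):
            isi = np.diff(np.sort(times[ids == nid]))
            if isi.size:
                assert isi.min() >= 1.0
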