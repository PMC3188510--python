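"""Network integration: determinism, latency, trials, perturbation."""
import numpy as np
import pytest

from hypercol.config import ConfigError, default_spec
from hypercol.inputs import Stimulus
from hypercol.simulate import (Recorders, perturb_single_spike, run,
                               run_trials)


class TestDeterminism:
    def test_same_seed_bit_identical(self, mini_spec):
        rec = Recorders(voltage_ids=(0, 5), lfp_sectors=((0.0, 9.0),),
                        warmup_ms=100.0)
        a = run(mini_spec, Stimulus(contrast=0.3), 800, rec, seed=3)
        b = run(mini_spec, Stimulus(contrast=0.3), 800, rec, seed=3)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        for k in a.traces:
            assert np.array_equal(a.traces[k].samples, b.traces[k].samples)

    def test_different_seeds_differ(self, mini_spec):
        a = run(mini_spec, Stimulus(contrast=0.3), 800, Recorders(), seed=3)
        b = run(mini_spec, Stimulus(contrast=0.3), 800, Recorders(), seed=4)
        assert not (a.spike_times.size == b.spike_times.size
                    and np.array_equal(a.spike_times, b.spike_times))

    def test_quiescent_without_drive(self):
        from dataclasses import replace
        spec = default_spec(n_exc=40, n_inh=10, probability_overflow="clip")
        lgn = replace(spec.lgn, rate_offset=0.0, rate_gain=0.0)
        bg = replace(spec.background, mean_rate=1e-9, volatility=0.0)
        spec = replace(spec, lgn=lgn, background=bg).validate()
        res = run(spec, Stimulus(contrast=0.0), 500, Recorders(warmup_ms=0.0),
                  seed=0)
        assert res.spike_ids.size == 0

    def test_relaxation_to_rest_without_conductances(self):
        """With all drives off, every membrane settles at its resting point."""
        from dataclasses import replace
        spec = default_spec(n_exc=40, n_inh=10, probability_overflow="clip")
        lgn = replace(spec.lgn, rate_offset=0.0, rate_gain=0.0)
        bg = replace(spec.background, mean_rate=1e-9, volatility=0.0)
        spec = replace(spec, lgn=lgn, background=bg).validate()
        res = run(spec, Stimulus(contrast=0.0), 600,
                  Recorders(voltage_ids=(0, 50, 99), warmup_ms=0.0), seed=1)
        for k, tr in res.traces.items():
            if k.startswith("v:"):
                assert tr.samples[-1] == pytest.approx(-57.8, abs=0.01)


class TestLatency:
    def test_single_presynaptic_spike_respects_pathway_delay(self):
        """A lone presynaptic spike changes postsynaptic input no earlier
        than its pathway latency (1 ms intra-layer at default)."""
        from dataclasses import replace
        spec = default_spec(n_exc=40, n_inh=10, probability_overflow="clip")
        lgn = replace(spec.lgn, rate_offset=0.0, rate_gain=0.0,
                      inhibitory_attenuation=1.0)
        bg = replace(spec.background, mean_rate=1e-9, volatility=0.0)
        spec = replace(spec, lgn=lgn, background=bg).validate()
        # drive exactly one excitatory neuron with a tonic conductance
        tonic = np.zeros(spec.n_total)
        tonic[0] = 40.0  # nS, suprathreshold
        rec = Recorders(current_ids=tuple(range(spec.n_total)), warmup_ms=0.0)
        res = run(spec, Stimulus(contrast=0.0), 200, rec, seed=2,
                  tonic_exc_conductance=tonic)
        spikes0 = res.spikes_of(0)
        assert spikes0.size > 0
        t0 = spikes0[0]
        moved = []
        for nid in range(1, spec.n_total):
            tr = res.traces[f"i:{nid}"].samples
            nz = np.nonzero(np.abs(tr) > 1e-12)[0]
            if nz.size:
                moved.append(nz[0] * res.dt)
        assert moved, "the spike reached no target"
        assert min(moved) >= t0 + 1.0 - res.dt - 1e-9

    def test_interlayer_latency_longer_downward(self, mini_spec):
        lat = {w.pathway.name: w.latency
               for w in __import__("hypercol.connectivity", fromlist=["x"])
               .build_network(mini_spec, np.random.default_rng(0)).wirings}
        assert lat["upperE->lowerE"] == 3.0
        assert lat["lowerE->upperE"] == 1.0
        assert lat["upperE->upperE"] == 1.0


class TestTrials:
    def test_trials_share_wiring_but_not_noise(self, mini_spec):
        trials = run_trials(mini_spec, Stimulus(contrast=0.5, flashed=True),
                            n_trials=2, duration_ms=600,
                            recorders=Recorders(warmup_ms=0.0))
        assert trials[0].wiring_hash == trials[1].wiring_hash
        assert not np.array_equal(trials[0].spike_times, trials[1].spike_times)

    def test_zero_trials_rejected(self, mini_spec):
        with pytest.raises(ConfigError):
            run_trials(mini_spec, Stimulus(contrast=0.5), n_trials=0)


class TestPerturbation:
    @pytest.fixture(scope="class")
    def pair(self, mini_spec):
        stim = Stimulus(contrast=0.95)
        probe = run(mini_spec, stim, 1500, Recorders(warmup_ms=500.0), seed=9)
        rates = probe.firing_rates()
        ui = probe.population_indices("upper_I")
        target = int(ui[np.argmax(rates[ui])])
        # index of this neuron's first post-warmup spike
        st = probe.spikes_of(target)
        idx = int(np.searchsorted(st, probe.warmup_ms))
        base, pert = perturb_single_spike(
            mini_spec, stim, 1500, 9, target, idx,
            Recorders(warmup_ms=0.0, lfp_sectors=((0.0, 9.0),)))
        return base, pert, target, st[idx]

    def test_identical_before_perturbed_spike(self, pair):
        base, pert, target, t_sp = pair
        nb = base.spike_times < t_sp
        npv = pert.spike_times < t_sp
        assert np.array_equal(base.spike_times[nb], pert.spike_times[npv])
        assert np.array_equal(base.spike_ids[nb], pert.spike_ids[npv])

    def test_emitter_still_resets(self, pair):
        base, pert, target, t_sp = pair
        # the omitted spike is still fired by the emitter itself
        assert np.any(np.isclose(pert.spikes_of(target), t_sp, atol=1e-9))

    def test_runs_eventually_differ(self, pair):
        base, pert, _, t_sp = pair
        after_b = base.spike_times[base.spike_times > t_sp]
        after_p = pert.spike_times[pert.spike_times > t_sp]
        assert (after_b.size != after_p.size
                or not np.allclose(after_b, after_p))

    def test_absent_spike_index_rejected(self, mini_spec):
        with pytest.raises(ConfigError, match="absent|fired only"):
            perturb_single_spike(mini_spec, Stimulus(contrast=0.95), 600, 9,
                                 target_neuron=0, target_spike_index=10_000)


class TestRecorders:
    def test_trace_lengths_match_duration(self, mini_run_low):
        res = mini_run_low
        n = int(round((res.duration_ms - res.warmup_ms) / res.dt))
        for tr in res.traces.values():
            assert len(tr) == n

    def test_streaming_chi_matches_offline_computation(self, mini_spec):
        from hypercol.analysis import synchrony_chi
        ue = __import__("hypercol.simulate", fromlist=["population_indices"]) \
            .population_indices(mini_spec, "upper_E")
        rec = Recorders(chi_populations=("upper_E",),
                        voltage_ids=tuple(ue), warmup_ms=200.0)
        res = run(mini_spec, Stimulus(contrast=0.95), 1200, rec, seed=5)
        vt = mini_spec.neurons["E"].v_threshold
        traces = np.vstack([np.minimum(res.traces[f"v:{i}"].samples, vt)
                            for i in ue])
        assert res.chi["upper_E"] == pytest.approx(synchrony_chi(traces),
                                                   rel=1e-9)

    def test_spike_times_strictly_increasing_per_neuron(self, mini_run_high):
        res = mini_run_high
        for nid in np.unique(res.spike_ids):
            st = res.spikes_of(nid)
            assert np.all(np.diff(st) > 0)
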