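"""Analysis battery: tuning, CRF, synchrony, correlations, spectra, PSTH."""
import math

import numpy as np
import pytest
from scipy import signal as sps

from hypercol.analysis import (AnalysisError, chi_scaling, coherence,
                               correlogram, fit_crf, lfp_signal,
                               mua_lfp_coherence, mua_signal, pairwise_cco,
                               power_spectrum, psth, smooth_spike_train,
                               synchrony_chi, tuning_statistics)
from hypercol.series import SignalSeries

GRID12 = np.linspace(-90, 90, 12, endpoint=False)


class TestTuning:
    def test_flat_curve_has_unit_circular_variance(self):
        tc = tuning_statistics(GRID12, np.full(12, 7.0))
        assert tc.circular_variance == pytest.approx(1.0)

    def test_single_orientation_perfectly_tuned(self):
        r = np.zeros(12)
        r[3] = 5.0
        tc = tuning_statistics(GRID12, r)
        assert tc.circular_variance == pytest.approx(0.0)
        assert tc.preferred == pytest.approx(GRID12[3])

    def test_rectified_cosine_matches_quadrature_oracle(self):
        psi = 15.0
        r = np.maximum(np.cos(np.deg2rad(2 * (GRID12 - psi))), 0.0)
        tc = tuning_statistics(GRID12, r)
        # oracle: same resultant computed by explicit summation
        z = np.sum(r * np.exp(2j * np.deg2rad(GRID12))) / np.sum(r)
        assert tc.circular_variance == pytest.approx(1 - abs(z), abs=1e-6)
        assert tc.skewness == pytest.approx(0.0, abs=1e-9)
        assert tc.preferred == pytest.approx(psi, abs=1e-6)

    def test_asymmetric_curve_has_signed_skewness(self):
        r = np.maximum(np.cos(np.deg2rad(2 * GRID12)), 0.0)
        r_skewed = r * (1.0 + 0.5 * np.sin(np.deg2rad(2 * GRID12)))
        tc = tuning_statistics(GRID12, r_skewed)
        assert tc.skewness != pytest.approx(0.0, abs=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            tuning_statistics(GRID12, np.zeros(12))


class TestCrf:
    def test_parameter_recovery_with_small_noise(self):
        rng = np.random.default_rng(0)
        c = np.concatenate([[0.001, 0.002], np.logspace(-2.5, 0, 14)])
        true = dict(r_max=30.0, c50=0.1, n=1.2, base=2.0)
        r = true["base"] + true["r_max"] * c**true["n"] / (c**true["n"] + true["c50"]**true["n"])
        r = r * (1 + 0.01 * rng.standard_normal(c.size))
        fit = fit_crf(c, r)
        assert fit["r_max"] == pytest.approx(30.0, rel=0.05)
        assert fit["c50"] == pytest.approx(0.1, rel=0.05)
        assert fit["exponent"] == pytest.approx(1.2, rel=0.05)
        assert fit["baseline"] == pytest.approx(2.0, abs=0.15)
        assert not fit["degenerate"]

    def test_constant_data_flagged_degenerate(self):
        fit = fit_crf(np.linspace(0.01, 1, 6), np.full(6, 4.0))
        assert fit["degenerate"]

    def test_fit_within_noise_envelope(self):
        rng = np.random.default_rng(1)
        c = np.logspace(-2, 0, 9)
        r = 20 * c / (c + 0.15) + rng.normal(0, 0.2, c.size)
        fit = fit_crf(c, r)
        assert fit["residual_rms"] < 3 * 0.2


class TestChi:
    def test_identical_traces_fully_synchronous(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        assert synchrony_chi(np.tile(x, (5, 1))) == pytest.approx(1.0)

    def test_independent_noise_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        for n in (8, 64):
            reps = [synchrony_chi(rng.standard_normal((n, 4000)))
                    for _ in range(20)]
            se = np.std(reps) / math.sqrt(len(reps))
            assert np.mean(reps) == pytest.approx(1 / math.sqrt(n), abs=3 * se + 0.01)

    def test_shared_plus_private_closed_form(self):
        rng = np.random.default_rng(2)
        n, t = 32, 20000
        shared = np.sin(2 * np.pi * np.arange(t) / 180.0) * math.sqrt(2.0)
        reps = [synchrony_chi(shared + rng.standard_normal((n, t)))
                for _ in range(10)]
        expected = math.sqrt((1 + 1.0 / n) / 2.0)
        se = np.std(reps) / math.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(expected, abs=3 * se + 0.01)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((6, 3000))
        assert synchrony_chi(3.5 * v - 60.0) == pytest.approx(synchrony_chi(v))

    def test_zero_variance_trace_rejected(self):
        with pytest.raises(AnalysisError):
            synchrony_chi(np.vstack([np.zeros(100), np.ones(100)]))


class TestChiScaling:
    def test_exact_power_law(self):
        n = np.array([500, 1000, 2000, 4000])
        fit = chi_scaling(n, [1 / math.sqrt(v) for v in n])
        assert fit["slope"] == pytest.approx(-0.5, abs=1e-9)
        assert fit["asymptote"] == pytest.approx(0.0, abs=1e-6)

    def test_saturating_form_recovers_asymptote(self):
        n = np.array([250, 500, 1000, 2000, 8000])
        chi = np.sqrt(0.25 + 1.0 / n)
        fit = chi_scaling(n, list(chi))
        assert fit["asymptote"] == pytest.approx(0.5, rel=0.01)

    def test_bootstrap_interval_covers_slope(self):
        rng = np.random.default_rng(0)
        n = np.array([500, 1000, 2000])
        chis = [list(1 / np.sqrt(v) * (1 + 0.05 * rng.standard_normal(5)))
                for v in n]
        fit = chi_scaling(n, chis, rng=1)
        lo, hi = fit["slope_ci"]
        # the interval brackets the point estimate and is informative
        assert lo <= fit["slope"] <= hi
        assert 0.0 < hi - lo < 0.5


class TestCorrelogram:
    def test_autocorrelogram_normalized_unity_at_zero(self):
        rng = np.random.default_rng(0)
        x = SignalSeries(rng.standard_normal(5000), 1000.0)
        lags, ac = correlogram(x, x, 50.0)
        assert ac[lags == 0.0] == pytest.approx(1.0)

    def test_sign_flip(self):
        rng = np.random.default_rng(1)
        x = SignalSeries(rng.standard_normal(5000), 1000.0)
        y = SignalSeries(-x.samples, 1000.0)
        _, cc = correlogram(x, y, 10.0)
        assert cc[10] == pytest.approx(-1.0)

    def test_unnormalized_zero_lag_is_variance(self):
        rng = np.random.default_rng(2)
        x = SignalSeries(3.0 * rng.standard_normal(10000), 1000.0)
        lags, ac = correlogram(x, x, 20.0, normalized=False)
        assert ac[lags == 0.0] == pytest.approx(x.samples.var(), rel=1e-9)

    def test_independent_ou_traces_uncorrelated(self, ou_series):
        rng = np.random.default_rng(3)
        a = np.exp(-1.0 / 10.0)
        other = np.empty_like(ou_series)
        other[0] = 0.0
        noise = rng.standard_normal(other.size) * math.sqrt(1 - a * a)
        for i in range(1, other.size):
            other[i] = a * other[i - 1] + noise[i]
        x = SignalSeries(ou_series, 1000.0)
        y = SignalSeries(other, 1000.0)
        _, cc = correlogram(x, y, 5.0)
        n_eff = ou_series.size / (2 * 10.0)
        assert abs(cc[5]) < 3.0 / math.sqrt(n_eff)

    def test_lag_bounds_checked(self):
        x = SignalSeries(np.arange(100, dtype=float), 1000.0)
        with pytest.raises(AnalysisError):
            correlogram(x, x, 200.0)


class TestPairwiseCco:
    def test_self_pair_unity(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 100_000, 1000))
        cc = pairwise_cco([spikes, spikes], "spikes", duration_ms=100_000)
        assert cc[0] == pytest.approx(1.0)

    def test_independent_poisson_mean_zero(self):
        rng = np.random.default_rng(1)
        trains = [np.sort(rng.uniform(0, 100_000, 1000)) for _ in range(12)]
        cc = pairwise_cco(trains, "spikes", duration_ms=100_000)
        se = np.std(cc) / math.sqrt(cc.size)
        assert np.mean(cc) == pytest.approx(0.0, abs=3 * se + 0.003)

    def test_common_rate_modulation_positive(self):
        rng = np.random.default_rng(2)
        t = np.arange(200_000)  # ms
        rate = (20.0 + 15.0 * np.sin(2 * np.pi * t / 400.0)) * 1e-3
        trains = [t[rng.random(t.size) < rate] + rng.random() for _ in range(8)]
        cc = pairwise_cco(trains, "spikes", duration_ms=200_000)
        assert np.mean(cc) > 0.05

    def test_min_spike_filter(self):
        rng = np.random.default_rng(3)
        sparse = np.sort(rng.uniform(0, 100_000, 10))
        with pytest.raises(AnalysisError, match="no admissible pairs"):
            pairwise_cco([sparse, sparse], "spikes", duration_ms=100_000)


class TestSpectra:
    def test_sinusoid_peak_at_its_frequency(self):
        fs = 5000.0
        t = np.arange(int(20 * fs / 2)) / fs
        x = SignalSeries(np.sin(2 * np.pi * 40.0 * t), fs)
        est = power_spectrum(x)
        assert est.frequencies[np.argmax(est.values)] == pytest.approx(40.0, abs=1.0)

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        x = SignalSeries(rng.standard_normal(100_000), 1000.0)
        est = power_spectrum(x)
        body = est.values[2:-2]
        # Welch with K segments: relative SD of each bin ~ 1/sqrt(K)
        k = 100_000 // 500
        assert body.std() / body.mean() < 3.0 / math.sqrt(k) + 0.1

    def test_ou_lorentzian_shape(self, ou_series):
        """Welch spectrum of an OU process follows the analytic AR(1)
        (discretized Lorentzian) curve, with half-power near 1/(2 pi tau)."""
        x = SignalSeries(ou_series, 1000.0)  # tau = 10 ms
        est = power_spectrum(x, segment_ms=2000.0)
        a = math.exp(-1.0 / 10.0)
        w = 2 * np.pi * est.frequencies / 1000.0
        analytic = (1 - a * a) / (1 - 2 * a * np.cos(w) + a * a)
        sel = (est.frequencies > 5) & (est.frequencies < 200)
        ratio = est.values[sel] / est.values[sel][0]
        ref = analytic[sel] / analytic[sel][0]
        assert np.median(np.abs(np.log(ratio / ref))) < 0.30
        # half-power frequency close to the Lorentzian corner 1/(2 pi tau)
        f0 = 1000.0 / (2 * np.pi * 10.0)
        corner = np.interp(f0, est.frequencies[sel], ref)
        assert 0.35 < corner < 0.65

    def test_wiener_khinchin_roundtrip(self):
        """FFT of the full autocorrelation equals the periodogram."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4096)
        x -= x.mean()
        n = x.size
        per = np.abs(np.fft.rfft(x))**2 / n
        ac_full = sps.correlate(x, x, mode="full") / n
        # circular equivalence requires zero-padded correlation transform
        ac_spec = np.fft.rfft(np.concatenate([x, np.zeros(n)]))
        per2 = np.abs(ac_spec)**2 / n
        back = np.fft.irfft(per2)[:n]
        assert np.allclose(back, ac_full[n - 1:], atol=1e-8)

    def test_normalization_against_reference(self):
        rng = np.random.default_rng(2)
        ref = SignalSeries(rng.standard_normal(20000), 1000.0)
        x = SignalSeries(2.0 * rng.standard_normal(20000), 1000.0)
        est = power_spectrum(x, reference=ref)
        est_ref = power_spectrum(ref, reference=ref)
        assert est_ref.values[1] == pytest.approx(1.0)
        assert est.values[1] == pytest.approx(4.0, rel=0.5)


class TestMuaAndCoherence:
    def test_mua_integral_counts_spikes(self, mini_run_low):
        mua = mua_signal(mini_run_low, 0.0, n_units=3, rng=0)
        total = mua.samples.sum()  # unit-integral kernel in sample units
        ids = mua.meta["units"]
        count = sum(((mini_run_low.spikes_of(i) >= mini_run_low.warmup_ms)
                     & (mini_run_low.spikes_of(i) < mini_run_low.duration_ms)).sum()
                    for i in ids)
        assert total == pytest.approx(count, abs=1e-6 * max(count, 1) + 1e-9)

    def test_coherence_of_identical_signals_is_one(self):
        rng = np.random.default_rng(0)
        x = SignalSeries(rng.standard_normal(10000), 1000.0)
        est = coherence(x, x)
        assert np.allclose(est.values, 1.0)

    def test_independent_signals_below_bias_floor(self):
        rng = np.random.default_rng(1)
        x = SignalSeries(rng.standard_normal(64000), 1000.0)
        y = SignalSeries(rng.standard_normal(64000), 1000.0)
        est = coherence(x, y)
        k = 64000 // 500  # Welch segments at 50% overlap ~ 2n/nper
        bias = 1.0 / math.sqrt(k)
        assert np.median(est.values) < 3 * bias

    def test_bandpass_relationship_elevates_band_only(self):
        rng = np.random.default_rng(2)
        fs = 1000.0
        x = rng.standard_normal(120_000)
        sos = sps.butter(4, [30, 60], "bandpass", fs=fs, output="sos")
        y = sps.sosfilt(sos, x) + 2.0 * rng.standard_normal(x.size)
        est = coherence(SignalSeries(x, fs), SignalSeries(y, fs))
        inband = est.values[est.band_mask(35, 55)].mean()
        outband = est.values[est.band_mask(100, 300)].mean()
        assert inband > 3 * outband

    def test_mua_lfp_coherence_range(self, mini_run_high):
        est = mua_lfp_coherence(mini_run_high, 0.0, n_triplets=5, rng=0)
        assert np.all((est.values >= 0) & (est.values <= 1))


class TestPsth:
    def test_poisson_bars_match_rate(self):
        rng = np.random.default_rng(0)
        rate, n_cells, n_trials, window = 10.0, 20, 200, 1500.0
        trials = []
        for _ in range(n_trials):
            lam = rate * 1e-3 * window
            counts = rng.poisson(lam, n_cells)
            trials.append(np.sort(rng.uniform(0, window, counts.sum())))
        edges, bars = psth(trials, n_cells=n_cells, bin_ms=2.0, window_ms=window)
        assert bars.mean() == pytest.approx(0.02, rel=0.05)

    def test_empty_trials_zero_histogram(self):
        edges, bars = psth([np.array([])] * 5, n_cells=3, bin_ms=2.0,
                           window_ms=100.0)
        assert np.all(bars == 0.0)

    def test_error_halves_with_four_times_trials(self):
        rng = np.random.default_rng(1)

        def se_of(n_trials):
            reps = []
            for _ in range(30):
                trials = [np.sort(rng.uniform(0, 200.0, rng.poisson(4)))
                          for _ in range(n_trials)]
                _, bars = psth(trials, n_cells=1, bin_ms=2.0, window_ms=200.0)
                reps.append(bars[5])
            return np.std(reps)

        assert se_of(160) == pytest.approx(0.5 * se_of(40), rel=0.6)

    def test_bin_must_divide_window(self):
        with pytest.raises(AnalysisError):
            psth([np.array([1.0])], n_cells=1, bin_ms=3.0, window_ms=100.0)


class TestLfpSignal:
    def test_single_neuron_sector_is_its_current(self, mini_run_low):
        res = mini_run_low
        # narrow sector around a recorded neuron's angle (chosen so that no
        # inhibitory grid point falls inside)
        nid = 10
        center = res.angles[nid]
        width = 0.5 * 180.0 / res.sizes[("upper", "E")]
        series = lfp_signal(res, center, width)
        assert np.allclose(series.samples, res.traces[f"i:{nid}"].samples)

    def test_recorded_channel_preferred(self, mini_run_low):
        series = lfp_signal(mini_run_low, 0.0, 9.0)
        assert series.meta["n_neurons"] > 1

    def test_sector_count_at_reference_size(self):
        """The default 9-degree LFP sector covers 200 excitatory and 50
        inhibitory upper-layer cells at the reference ring density."""
        from hypercol.connectivity import population_angles, wrap_angle
        a_e = population_angles(4000)
        a_i = population_angles(1000)
        d_e = wrap_angle(a_e - 0.0)
        d_i = wrap_angle(a_i - 0.0)
        n_e = np.sum((d_e >= -4.5) & (d_e < 4.5))
        n_i = np.sum((d_i >= -4.5) & (d_i < 4.5))
        assert (n_e, n_i) == (200, 50)
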