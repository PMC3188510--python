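"""Steady-state and trial-based statistics of the hypercolumn.

Covers the whole battery: orientation-tuning summaries (circular variance and
skewness), hyperbolic-ratio contrast-response fits, the voltage synchrony
measure chi and its finite-size scaling, auto/cross-correlograms and pairwise
zero-lag correlation coefficients for spike trains and voltages, LFP and MUA
construction from simulation results, Welch power spectra, MUA-LFP coherence
and peristimulus time histograms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .connectivity import wrap_angle
from .series import SignalSeries

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimulationResult

__all__ = [
    "TuningCurve", "SpectralEstimate", "AnalysisError",
    "tuning_statistics", "fit_crf", "synchrony_chi", "chi_scaling",
    "correlogram", "pairwise_cco", "smooth_spike_train",
    "lfp_signal", "power_spectrum", "mua_signal", "mua_lfp_coherence", "psth",
]


class AnalysisError(ValueError):
    pass


# --------------------------------------------------------------------------
# orientation tuning
# --------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Rates by orientation plus circular summary statistics.

    ``circular_variance`` is one minus the modulus of the orientation-doubled
    resultant (0 = perfectly tuned, 1 = flat); ``skewness`` is the weighted
    third moment of the wrapped deviation from the preferred orientation,
    normalized by the 3/2 power of the second moment (0 for symmetric
    curves).
    """

    orientations: np.ndarray
    rates: np.ndarray
    peak_rate: float
    preferred: float
    circular_variance: float
    skewness: float


def tuning_statistics(orientations_deg, rates) -> TuningCurve:
    th = np.asarray(orientations_deg, dtype=float)
    r = np.asarray(rates, dtype=float)
    if th.size < 3:
        raise AnalysisError("need at least 3 orientations")
    if th.shape != r.shape:
        raise AnalysisError("orientations and rates must align")
    if np.all(r == 0):
        raise AnalysisError("all-zero tuning curve")
    if np.any(r < 0):
        raise AnalysisError("rates must be >= 0")
    z = np.sum(r * np.exp(2j * np.deg2rad(th)))
    m = z / np.sum(r)
    cv = 1.0 - abs(m)
    psi = math.degrees(math.atan2(m.imag, m.real) / 2.0)
    d = wrap_angle(th - psi)
    w = r / r.sum()
    mu2 = np.sum(w * d**2)
    mu3 = np.sum(w * d**3)
    gamma = 0.0 if mu2 == 0 else float(mu3 / mu2**1.5)
    return TuningCurve(orientations=th, rates=r, peak_rate=float(r.max()),
                       preferred=float(psi), circular_variance=float(cv),
                       skewness=gamma)


def fit_crf(contrasts, peak_rates, p0=None):
    """Least-squares fit of the hyperbolic-ratio (Naka-Rushton) contrast
    response R(C) = baseline + R_max * C^n / (C^n + C50^n).

    Returns a dict with the parameters, their 1-sigma errors, the residual
    RMS and a ``degenerate`` flag (set when C50 is unidentifiable, e.g. for
    constant data).
    """
    c = np.asarray(contrasts, dtype=float)
    r = np.asarray(peak_rates, dtype=float)
    if c.size < 5:
        raise AnalysisError("need at least 5 contrast levels")
    span = r.max() - r.min()
    if span <= 1e-12 * max(1.0, abs(r.max())):
        return {"r_max": 0.0, "c50": np.nan, "exponent": np.nan,
                "baseline": float(r.mean()), "residual_rms": 0.0,
                "degenerate": True, "errors": None}

    def model(cc, rmax, c50, n, base):
        cc = np.maximum(cc, 1e-12)
        return base + rmax * cc**n / (cc**n + c50**n)

    if p0 is None:
        p0 = (span, max(np.median(c), 1e-3), 1.5, r.min())
    try:
        popt, pcov = curve_fit(
            model, c, r, p0=p0, maxfev=20000,
            bounds=([0.0, 1e-6, 0.1, -np.inf], [np.inf, 10.0, 10.0, np.inf]))
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise AnalysisError(f"CRF fit did not converge: {exc}") from None
    resid = r - model(c, *popt)
    errs = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    degenerate = not np.all(np.isfinite(errs)) or errs[1] > 10.0 * popt[1]
    return {"r_max": float(popt[0]), "c50": float(popt[1]),
            "exponent": float(popt[2]), "baseline": float(popt[3]),
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "degenerate": bool(degenerate),
            "errors": {"r_max": float(errs[0]), "c50": float(errs[1]),
                       "exponent": float(errs[2]), "baseline": float(errs[3])}}


# --------------------------------------------------------------------------
# synchrony
# --------------------------------------------------------------------------

def synchrony_chi(voltage_traces) -> float:
    """Ratio-of-variances synchrony measure over a population of traces.

    chi^2 = Var_t[population-mean V] / mean_i Var_t[V_i]; 1 for identical
    traces, ~N^{-1/2} for independent ones.  Invariant under common affine
    transforms of all traces.
    """
    v = np.asarray(voltage_traces, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise AnalysisError("need >= 2 traces of equal length")
    var_i = v.var(axis=1)
    if np.any(var_i == 0):
        raise AnalysisError("trace with zero variance")
    var_mean = v.mean(axis=0).var()
    return float(math.sqrt(var_mean / var_i.mean()))


def chi_scaling(sizes, chis, n_boot: int = 200, rng=None):
    """Fit chi(N) = sqrt(a + b/N) and the log-log slope of the decay.

    Returns asymptote sqrt(a), the fitted b, the log-log slope over the
    sampled sizes, and a bootstrap CI of the slope when multiple chi values
    per size are supplied.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 3:
        raise AnalysisError("need at least 3 sizes")
    chim = np.array([np.mean(c) for c in chis], dtype=float)
    y = chim**2
    A = np.vstack([np.ones_like(sizes), 1.0 / sizes]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = max(coef[0], 0.0), coef[1]
    slope = float(np.polyfit(np.log(sizes), np.log(chim), 1)[0])
    ci = None
    lens = [np.size(c) for c in chis]
    if min(lens) > 1:
        rng = np.random.default_rng(rng)
        boots = []
        for _ in range(n_boot):
            samp = [np.mean(rng.choice(np.atleast_1d(c), size=np.size(c)))
                    for c in chis]
            boots.append(np.polyfit(np.log(sizes), np.log(samp), 1)[0])
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return {"asymptote": float(math.sqrt(a)), "b": float(b), "slope": slope,
            "slope_ci": ci}


# --------------------------------------------------------------------------
# correlograms and pairwise correlation coefficients
# --------------------------------------------------------------------------

def correlogram(x: SignalSeries, y: SignalSeries, max_lag_ms: float,
                normalized: bool = True):
    """Cross-covariance of the mean-subtracted signals over lags up to
    ``max_lag_ms``; ``correlogram(x, x)`` is the autocorrelogram whose
    unnormalized zero-lag value is the signal variance.

    Returns (lags_ms, values); normalization divides by the geometric mean
    of the two variances.
    """
    if x.fs_hz != y.fs_hz:
        raise AnalysisError("sampling rates differ")
    if len(x) != len(y):
        raise AnalysisError("series lengths differ")
    nlag = int(round(max_lag_ms / x.dt_ms))
    n = len(x)
    if nlag >= n:
        raise AnalysisError("max_lag exceeds series length")
    a = x.samples - x.samples.mean()
    b = y.samples - y.samples.mean()
    full = sps.correlate(a, b, mode="full", method="auto") / n
    mid = n - 1
    vals = full[mid - nlag: mid + nlag + 1]
    lags = np.arange(-nlag, nlag + 1) * x.dt_ms
    if normalized:
        denom = math.sqrt(a.var() * b.var())
        if denom == 0:
            raise AnalysisError("zero-variance input")
        vals = vals / denom
    return lags, vals


def smooth_spike_train(spike_times_ms, duration_ms: float, fs_hz: float = 1000.0,
                       window_ms: float = 10.0) -> SignalSeries:
    """Convolve a spike train with a square window -> continuous spike-count
    signal (the smoothing applied before spike-train correlations)."""
    dt = 1000.0 / fs_hz
    n = int(round(duration_ms / dt))
    counts = np.zeros(n)
    idx = np.floor(np.asarray(spike_times_ms) / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(counts, idx, 1.0)
    w = max(1, int(round(window_ms / dt)))
    kern = np.ones(w) / w
    sm = np.convolve(counts, kern, mode="same")
    return SignalSeries(sm, fs_hz, "spikes/bin", {"window_ms": window_ms})


def pairwise_cco(trains_or_traces, kind: str = "spikes", *,
                 duration_ms: float | None = None, fs_hz: float = 1000.0,
                 window_ms: float = 10.0, min_spikes: int = 100):
    """Zero-lag normalized correlation coefficients over all admissible pairs.

    ``kind='spikes'`` takes a sequence of spike-time arrays, convolves each
    with a square window and drops trains with fewer than ``min_spikes``
    events; ``kind='voltage'`` takes raw traces.  Selection of the neurons
    (angular sector around the stimulus) is the caller's responsibility.
    """
    series: list[np.ndarray] = []
    if kind == "spikes":
        if duration_ms is None:
            raise AnalysisError("duration_ms required for spike trains")
        for st in trains_or_traces:
            st = np.asarray(st)
            if st.size < min_spikes:
                continue
            series.append(smooth_spike_train(st, duration_ms, fs_hz, window_ms).samples)
    elif kind == "voltage":
        series = [np.asarray(t, dtype=float) for t in trains_or_traces]
    else:
        raise AnalysisError(f"unknown kind {kind!r}")
    if len(series) < 2:
        raise AnalysisError("no admissible pairs")
    mat = np.vstack(series)
    mat = mat - mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        keep = sd > 0
        mat, sd = mat[keep], sd[keep]
        if mat.shape[0] < 2:
            raise AnalysisError("no admissible pairs")
    corr = (mat @ mat.T) / mat.shape[1] / np.outer(sd, sd)
    iu = np.triu_indices(mat.shape[0], k=1)
    return corr[iu]


# --------------------------------------------------------------------------
# LFP / MUA / spectra / coherence
# --------------------------------------------------------------------------

def _sector_indices(result: "SimulationResult", center: float, width: float,
                    layer: str = "upper") -> np.ndarray:
    parts = []
    for pop in (f"{layer}_E", f"{layer}_I"):
        idx = result.population_indices(pop)
        d = wrap_angle(result.angles[idx] - center)
        parts.append(idx[(d >= -width / 2.0) & (d < width / 2.0)])
    return np.concatenate(parts)


def lfp_signal(result: "SimulationResult", sector_center: float,
               sector_width: float = 9.0) -> SignalSeries:
    """Average total synaptic input current [nA] over the upper-layer
    neurons of an angular sector (the model's LFP proxy).

    Uses the channel recorded during the run when one matches; otherwise
    averages recorded per-neuron current traces covering the sector.  The
    default 9-degree sector covers 200 excitatory and 50 inhibitory
    upper-layer cells at the reference size.
    """
    key = f"lfp:{sector_center:g}:{sector_width:g}"
    if key in result.traces:
        return result.traces[key]
    idx = _sector_indices(result, sector_center, sector_width)
    if idx.size == 0:
        raise AnalysisError("empty LFP sector")
    traces = []
    for nid in idx:
        t = result.traces.get(f"i:{nid}")
        if t is None:
            raise AnalysisError(
                "synaptic-current recording not enabled for this sector")
        traces.append(t.samples)
    fs = result.traces[f"i:{idx[0]}"].fs_hz
    return SignalSeries(np.mean(traces, axis=0), fs, "nA",
                        {"sector_center": sector_center,
                         "sector_width": sector_width, "n_neurons": int(idx.size)})


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray
    values: np.ndarray  # power (normalized) or coherence in [0, 1]
    kind: str  # "power" | "coherence"
    normalization: str = ""

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.frequencies >= lo_hz) & (self.frequencies <= hi_hz)


def power_spectrum(x: SignalSeries, reference: SignalSeries | None = None,
                   segment_ms: float = 1000.0, smooth_bins: int = 0) -> SpectralEstimate:
    """Welch power spectrum (Hann taper, 50% overlap).

    When a zero-contrast ``reference`` series is given, power is normalized
    so that the reference's 0 Hz power equals one; otherwise the series' own
    0 Hz power is the unit.  ``smooth_bins`` applies a moving average for
    display.
    """
    nper = int(round(segment_ms / x.dt_ms))
    if len(x) < 4 * nper // 2:
        raise AnalysisError("series too short for the Welch segment length")
    f, p = sps.welch(x.samples - x.samples.mean(), fs=x.fs_hz, nperseg=nper,
                     noverlap=nper // 2, window="hann", detrend=False)
    # 0 Hz power of the *raw* (not mean-subtracted) signal is degenerate;
    # use the lowest nonzero bin as the "0 Hz" anchor of the convention
    if reference is not None:
        fr, pr = sps.welch(reference.samples - reference.samples.mean(),
                           fs=reference.fs_hz, nperseg=nper,
                           noverlap=nper // 2, window="hann", detrend=False)
        anchor = pr[1]
        norm = "unit power at 0 Hz of the zero-contrast reference"
    else:
        anchor = p[1]
        norm = "unit power at 0 Hz (own)"
    vals = p / anchor if anchor > 0 else p
    if smooth_bins and smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        vals = np.convolve(vals, k, mode="same")
    return SpectralEstimate(f, vals, "power", norm)


def mua_signal(result: "SimulationResult", sector_center: float,
               n_units: int = 3, rng=None, sector_width: float = 9.0,
               fs_hz: float = 5000.0, sigma_ms: float = 1.0) -> SignalSeries:
    """Multi-unit activity: the summed spike trains of ``n_units`` randomly
    chosen cells of the sector, convolved with a unit-integral Gaussian
    (1 ms standard deviation), sampled at 5 kHz."""
    rng = np.random.default_rng(rng)
    idx = _sector_indices(result, sector_center, sector_width)
    if idx.size < n_units:
        raise AnalysisError("fewer cells in the sector than requested units")
    chosen = rng.choice(idx, size=n_units, replace=False)
    dt = 1000.0 / fs_hz
    t0, t1 = result.warmup_ms, result.duration_ms
    n = int(round((t1 - t0) / dt))
    counts = np.zeros(n)
    for nid in chosen:
        st = result.spikes_of(int(nid))
        st = st[(st >= t0) & (st < t1)]
        k = np.floor((st - t0) / dt).astype(int)
        np.add.at(counts, k[(k >= 0) & (k < n)], 1.0)
    sig_bins = sigma_ms / dt
    half = int(math.ceil(6 * sig_bins))
    g = np.exp(-0.5 * (np.arange(-half, half + 1) / sig_bins) ** 2)
    g /= g.sum()  # unit integral in units of samples (counts preserved)
    sm = np.convolve(counts, g, mode="same")
    return SignalSeries(sm, fs_hz, "spikes/sample",
                        {"units": [int(c) for c in chosen],
                         "sector_center": sector_center})


def coherence(x: SignalSeries, y: SignalSeries,
              segment_ms: float = 1000.0) -> SpectralEstimate:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy) via Welch cross-spectra."""
    if x.fs_hz != y.fs_hz or len(x) != len(y):
        raise AnalysisError("series must share sampling rate and length")
    nper = int(round(segment_ms / x.dt_ms))
    if len(x) < 2 * nper:
        raise AnalysisError("series too short for coherence estimation")
    f, cxy = sps.coherence(x.samples, y.samples, fs=x.fs_hz, nperseg=nper,
                           noverlap=nper // 2, window="hann", detrend="constant")
    vals = np.sqrt(np.clip(cxy, 0.0, 1.0))
    return SpectralEstimate(f, vals, "coherence")


def mua_lfp_coherence(result: "SimulationResult", sector_center: float,
                      n_triplets: int = 20, rng=None, n_units: int = 3,
                      sector_width: float = 9.0,
                      segment_ms: float = 1000.0) -> SpectralEstimate:
    """MUA-LFP magnitude coherence at one site, averaged over randomly chosen
    cell triplets (values in [0, 1])."""
    rng = np.random.default_rng(rng)
    lfp = lfp_signal(result, sector_center, sector_width)
    acc = None
    f = None
    used = 0
    attempts = 0
    while used < n_triplets and attempts < 10 * n_triplets:
        attempts += 1
        mua = mua_signal(result, sector_center, n_units=n_units, rng=rng,
                         sector_width=sector_width, fs_hz=lfp.fs_hz)
        if mua.samples.std() == 0.0:
            continue  # all three cells silent: coherence undefined
        if len(mua) != len(lfp):
            m = min(len(mua), len(lfp))
            mua = SignalSeries(mua.samples[:m], mua.fs_hz)
            lfp = SignalSeries(lfp.samples[:m], lfp.fs_hz, lfp.units, lfp.meta)
        est = coherence(lfp, mua, segment_ms)
        f = est.frequencies
        acc = est.values if acc is None else acc + est.values
        used += 1
    if used == 0:
        raise AnalysisError("no spiking triplets in the sector")
    return SpectralEstimate(f, acc / used, "coherence",
                            f"average over {used} triplets")


# --------------------------------------------------------------------------
# PSTH
# --------------------------------------------------------------------------

def psth(trial_spike_times: Sequence, n_cells: int, bin_ms: float = 2.0,
         window_ms: float | None = None):
    """Peristimulus time histogram.

    ``trial_spike_times``: one array of stimulus-aligned spike times [ms] per
    trial, pooled over the sampled cells.  Each bar is (spike count in bin) /
    (number of trials) / (number of sampled cells), exactly.
    Returns (bin_edges_ms, bars).
    """
    n_trials = len(trial_spike_times)
    if n_trials < 1:
        raise AnalysisError("need at least one trial")
    if n_cells < 1:
        raise AnalysisError("need at least one sampled cell")
    if window_ms is None:
        window_ms = max((np.max(t) if np.size(t) else 0.0)
                        for t in trial_spike_times)
        window_ms = bin_ms * math.ceil(window_ms / bin_ms + 1e-9)
    if window_ms <= 0:
        window_ms = bin_ms
    n_bins = window_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise AnalysisError("bin width must divide the window")
    edges = np.arange(0.0, window_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    for t in trial_spike_times:
        h, _ = np.histogram(np.asarray(t), bins=edges)
        counts += h
    return edges, counts / n_trials / n_cells
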