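"""Nonlinear time-series analysis of LFP recordings.

Delay embedding of a scalar series, false-nearest-neighbor estimation of the
minimal embedding dimension, the neighbor-divergence curve S(dn) (the mean
log distance at horizon dn between trajectories that started epsilon-close),
and extraction of the largest Lyapunov exponent as the common slope of the
linear sections of S(dn) across embedding dimensions.  A positive, stable,
dimension-consistent linear region is the operational signature of
deterministic chaos; periodic signals and stochastic processes yield a
"no linear scaling region" verdict instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .series import SignalSeries

__all__ = [
    "EmbeddingSet", "DivergenceCurve", "LyapunovEstimate",
    "delay_embed", "autocorrelation_delay", "false_nearest_neighbors",
    "divergence_curve", "estimate_lambda_max", "phase_randomized_surrogate",
]


class ChaosError(ValueError):
    pass


@dataclass
class EmbeddingSet:
    """Delay-embedded vectors s_n = (x_n, x_{n-tau}, ..., x_{n-(m-1)tau})."""

    vectors: np.ndarray  # (n_vectors, m)
    dimension: int
    delay: int  # samples
    sample_period_ms: float
    source: str = ""
    theiler: int = 0

    def __len__(self) -> int:
        return self.vectors.shape[0]


def delay_embed(x, m: int, tau: int, sample_period_ms: float = 1.0,
                source: str = "", theiler: int = 0) -> EmbeddingSet:
    """Construct the lagged-coordinate embedding of a scalar series."""
    if isinstance(x, SignalSeries):
        sample_period_ms = x.dt_ms
        x = x.samples
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise ChaosError("need m >= 1 and tau >= 1")
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ChaosError("series too short for this embedding")
    # column j holds x_{n - j*tau}; vector index i corresponds to n = (m-1)tau + i
    vec = np.column_stack([x[(m - 1 - j) * tau: x.size - j * tau]
                           for j in range(m)])
    return EmbeddingSet(vectors=vec, dimension=m, delay=tau,
                        sample_period_ms=sample_period_ms, source=source,
                        theiler=theiler)


def autocorrelation_delay(x: SignalSeries | np.ndarray, max_lag: int = 5000) -> int:
    """Default reconstruction delay: the first zero crossing of the signal
    autocorrelation (in samples)."""
    s = x.samples if isinstance(x, SignalSeries) else np.asarray(x, dtype=float)
    s = s - s.mean()
    n = min(max_lag, s.size - 1)
    ac = np.array([np.dot(s[:s.size - k], s[k:]) for k in range(n)])
    below = np.nonzero(ac <= 0)[0]
    return int(below[0]) if below.size else max(1, n // 4)


def false_nearest_neighbors(x, tau: int, m_range, ratio_threshold: float = 10.0,
                            candidate_pairs: int = 1000, theiler: int = 10,
                            rng=None, sample_period_ms: float = 1.0) -> dict:
    """Fraction of false nearest neighbors per embedding dimension.

    A nearest-neighbor pair in dimension m is "false" when its separation
    grows by more than ``ratio_threshold`` upon extending the embedding to
    m+1 -- the signature of a projection artifact.  Neighbors closer than the
    Theiler window in time are excluded.
    """
    if isinstance(x, SignalSeries):
        sample_period_ms = x.dt_ms
        x = x.samples
    x = np.asarray(x, dtype=float)
    m_range = list(m_range)
    if not m_range:
        raise ChaosError("empty m_range")
    rng = np.random.default_rng(rng)
    out = {}
    for m in m_range:
        emb = delay_embed(x, m, tau)
        emb1 = delay_embed(x, m + 1, tau)
        # align reference times: vector i of the m-embedding is time
        # (m-1)tau + i, so dropping the first tau vectors matches emb1
        v = emb.vectors[tau:]
        v1 = emb1.vectors
        npts = min(v.shape[0], v1.shape[0])
        v, v1 = v[:npts], v1[:npts]
        if npts < 4 * theiler:
            raise ChaosError("not enough points for FNN")
        tree = cKDTree(v)
        k = min(2 * theiler + 5, npts)
        refs = (np.arange(npts) if npts <= candidate_pairs
                else np.sort(rng.choice(npts, size=candidate_pairs, replace=False)))
        dist, idx = tree.query(v[refs], k=k)
        floor = 1e-7 * float(np.std(x)) * math.sqrt(m)
        n_false = 0
        n_tot = 0
        for row, ref in enumerate(refs):
            hit = -1
            for j in range(1, k):
                if abs(int(idx[row, j]) - int(ref)) > theiler:
                    hit = j
                    break
            if hit < 0:
                continue
            nn = int(idx[row, hit])
            d_m = dist[row, hit]
            d_new = abs(v1[ref, -1] - v1[nn, -1])
            n_tot += 1
            if d_m <= floor:
                # numerically coincident points (e.g. exactly periodic
                # signals) are genuine neighbors, never projection artifacts
                continue
            if d_new / d_m > ratio_threshold:
                n_false += 1
        if n_tot == 0:
            raise ChaosError("no admissible neighbor pairs")
        out[m] = n_false / n_tot
    return out


@dataclass
class DivergenceCurve:
    """S(dn) for one embedding dimension."""

    horizons: np.ndarray  # samples
    s_values: np.ndarray  # natural log mean divergence
    epsilon: float
    n_reference: int
    dimension: int
    sample_period_ms: float
    meta: dict = field(default_factory=dict)


def divergence_curve(embedding: EmbeddingSet, epsilon: float, horizon: int,
                     min_pairs: int = 1000, theiler: int | None = None,
                     max_reference: int = 4000, rng=None) -> DivergenceCurve:
    """Neighbor-divergence curve: for reference points with at least one
    epsilon-neighbor (Theiler-excluded), S(dn) is the mean over references of
    the log of the mean distance of the neighborhood after dn steps."""
    v = embedding.vectors
    npts = v.shape[0] - horizon
    if npts < 10:
        raise ChaosError("embedding too short for this horizon")
    theiler = embedding.theiler if theiler is None else theiler
    rng = np.random.default_rng(rng)
    tree = cKDTree(v[:npts])
    refs = (np.arange(npts) if npts <= max_reference
            else np.sort(rng.choice(npts, size=max_reference, replace=False)))
    neigh = tree.query_ball_point(v[refs], r=epsilon)
    pairs = []
    for row, ref in enumerate(refs):
        good = [j for j in neigh[row] if abs(j - ref) > theiler and j < npts]
        if good:
            pairs.append((ref, np.asarray(good)))
    n_pairs = sum(len(g) for _, g in pairs)
    if n_pairs < min_pairs:
        raise ChaosError(
            f"only {n_pairs} neighbor pairs within epsilon (need {min_pairs}); "
            f"increase epsilon or the recording length")
    horizons = np.arange(horizon + 1)
    s = np.empty(horizons.size)
    for h in horizons:
        logs = []
        for ref, good in pairs:
            d = np.linalg.norm(v[good + h] - v[ref + h], axis=1)
            md = d.mean()
            if md > 0:
                logs.append(math.log(md))
        s[h] = float(np.mean(logs))
    return DivergenceCurve(horizons=horizons, s_values=s, epsilon=epsilon,
                           n_reference=len(pairs), dimension=embedding.dimension,
                           sample_period_ms=embedding.sample_period_ms,
                           meta={"n_pairs": n_pairs, "theiler": theiler})


@dataclass
class LyapunovEstimate:
    lambda_max: float | None  # 1/ms, None when no linear region
    verdict: str  # "chaotic" | "no linear scaling region"
    per_dimension_slopes: dict
    window: tuple | None
    diagnostics: dict = field(default_factory=dict)


def _linear_region(curve: DivergenceCurve, min_len: int = 5,
                   slope_tol: float = 0.20, min_rise: float = 0.5):
    """Longest window of stable positive local slope; None when absent."""
    s = curve.s_values
    if s.size < min_len + 2:
        return None
    local = np.gradient(s)
    best = None
    n = s.size
    i = 1  # skip the initial jump at dn = 0
    for start in range(i, n - min_len):
        for stop in range(start + min_len, n + 1):
            seg = local[start:stop]
            mseg = seg.mean()
            if mseg <= 0:
                break
            if np.any(seg <= 0) or np.max(np.abs(seg - mseg)) > slope_tol * abs(mseg):
                break
            rise = s[stop - 1] - s[start]
            if rise >= min_rise:
                cand = (stop - start, start, stop, (s[stop - 1] - s[start]) / (stop - 1 - start))
                if best is None or cand[0] > best[0]:
                    best = cand
    if best is None:
        return None
    _, start, stop, slope = best
    return {"start": start, "stop": stop, "slope_per_sample": slope}


def estimate_lambda_max(curves, min_len: int = 5, slope_tol: float = 0.20,
                        dim_tol: float = 0.20, min_rise: float = 0.5) -> LyapunovEstimate:
    """Largest Lyapunov exponent from divergence curves at >= 2 embedding
    dimensions: the mean slope of the common linear region, converted to
    1/ms; verdict "no linear scaling region" when slopes are absent or
    disagree across dimensions by more than ``dim_tol``."""
    curves = list(curves)
    if len(curves) < 2:
        raise ChaosError("need divergence curves for at least 2 dimensions")
    slopes = {}
    windows = {}
    for c in curves:
        reg = _linear_region(c, min_len=min_len, slope_tol=slope_tol,
                             min_rise=min_rise)
        if reg is not None:
            slopes[c.dimension] = reg["slope_per_sample"]
            windows[c.dimension] = (reg["start"], reg["stop"])
    diag = {"slopes_per_sample": dict(slopes), "windows": dict(windows)}
    if len(slopes) < 2:
        return LyapunovEstimate(None, "no linear scaling region", slopes, None, diag)
    vals = np.array(list(slopes.values()))
    mean = vals.mean()
    if np.max(np.abs(vals - mean)) > dim_tol * abs(mean):
        return LyapunovEstimate(None, "no linear scaling region", slopes, None, diag)
    period = curves[0].sample_period_ms
    lam = float(mean / period)
    w = windows[min(windows)]
    return LyapunovEstimate(lam, "chaotic", slopes, w, diag)


def auto_epsilon(embedding: EmbeddingSet, quantile: float = 10.0,
                 factor: float = 2.0, sample: int = 2000, rng=None) -> float:
    """Neighborhood radius heuristic: ``factor`` times the given percentile
    of nearest-neighbor distances over a sample of points."""
    rng = np.random.default_rng(rng)
    v = embedding.vectors
    idx = (np.arange(v.shape[0]) if v.shape[0] <= sample
           else rng.choice(v.shape[0], size=sample, replace=False))
    tree = cKDTree(v)
    d, _ = tree.query(v[idx], k=2)
    nn = d[:, 1]
    nn = nn[nn > 0]
    if nn.size == 0:
        raise ChaosError("degenerate embedding: all points coincide")
    return factor * float(np.percentile(nn, quantile))


def phase_randomized_surrogate(x, rng=None) -> np.ndarray:
    """Surrogate with the same power spectrum but randomized Fourier phases
    (destroys deterministic structure while keeping linear correlations)."""
    s = x.samples if isinstance(x, SignalSeries) else np.asarray(x, dtype=float)
    rng = np.random.default_rng(rng)
    spec = np.fft.rfft(s - s.mean())
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.size)
    phases[0] = 0.0
    if s.size % 2 == 0:
        phases[-1] = 0.0
    surr = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=s.size)
    return surr + s.mean()
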