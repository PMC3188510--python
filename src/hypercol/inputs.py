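"""External drives: tuned LGN Poisson input and shared-rate OU background.

The LGN drive is a homogeneous Poisson train per cortical cell through an
AMPA-type synapse.  A single afferent's rate grows logarithmically with
contrast from its dark rate (5 Hz) toward saturation (48 Hz); the population
rate seen by the cell at preferred-orientation distance dtheta is

    nu(theta, C) = attn * ( nu0 + nu1 * n(C) * [(1-eps) + eps cos 2(theta-theta0)]_+ )

with n(C) = ln(1 + beta C)/ln(1 + beta) the normalized contrast response,
nu0 = 150 Hz the untuned dark component, nu1 = 2850 Hz the tuned gain, and
attn = 1 (upper layer) or 0.5 (lower layer).  Contrast may be a square wave
in time (0.5 s on / 1 s off) for peristimulus protocols.

The background is one AMPA synapse per cell driven by independent Poisson
trains whose instantaneous rate R_bg(t) is shared by all cells and follows
an Ornstein-Uhlenbeck process (mean 10 Hz, stationary SD 1 Hz, correlation
time 10 ms), advanced with the exact discretization and rectified at zero
only when generating spikes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import BackgroundParams, ConfigError, LGNParams

__all__ = [
    "Stimulus",
    "BackgroundRateState",
    "lgn_single_cell_rate",
    "lgn_population_rate",
    "ou_rate_step",
    "ou_stationary_sd",
    "generate_input_spikes",
]


@dataclass(frozen=True)
class Stimulus:
    """Visual stimulus: contrast in [0, 1] and orientation [deg].

    With ``flashed=True`` the contrast follows a square wave: ``on_ms`` at
    ``contrast`` then ``off_ms`` at zero, repeating from t = 0 (instantaneous
    transitions).
    """

    contrast: float
    orientation: float = 0.0
    flashed: bool = False
    on_ms: float = 500.0
    off_ms: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigError("contrast must lie in [0, 1]")
        if self.flashed and (self.on_ms <= 0 or self.off_ms <= 0):
            raise ConfigError("flash phase durations must be > 0")

    def contrast_at(self, t_ms):
        """Contrast at time(s) ``t_ms``."""
        if not self.flashed:
            return np.broadcast_to(np.float64(self.contrast),
                                   np.shape(t_ms)).copy() if np.ndim(t_ms) else self.contrast
        phase = np.asarray(t_ms, dtype=float) % (self.on_ms + self.off_ms)
        return np.where(phase < self.on_ms, self.contrast, 0.0)


def normalized_contrast_response(contrast, params: LGNParams):
    """n(C) = ln(1 + beta C)/ln(1 + beta), monotone from 0 to 1."""
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ConfigError("contrast must lie in [0, 1]")
    beta = params.contrast_log_scale
    return np.log1p(beta * c) / math.log1p(beta)


def lgn_single_cell_rate(contrast, params: LGNParams = LGNParams()):
    """Firing rate [Hz] of a single LGN afferent at the given contrast."""
    n = normalized_contrast_response(contrast, params)
    return params.dark_rate + (params.max_rate - params.dark_rate) * n


def lgn_population_rate(theta_deg, stimulus: Stimulus, params: LGNParams,
                        layer: str = "upper", t_ms=None):
    """Poisson rate [Hz] of the LGN synapse of a cortical cell at preferred
    orientation ``theta_deg``."""
    theta = np.asarray(theta_deg, dtype=float)
    eps = params.tuning_broadness
    tuning = np.maximum(
        (1.0 - eps) + eps * np.cos(np.deg2rad(2.0 * (theta - stimulus.orientation))),
        0.0)
    c = stimulus.contrast if t_ms is None else stimulus.contrast_at(t_ms)
    n = normalized_contrast_response(c, params)
    rate = params.rate_offset + params.rate_gain * n * tuning
    if layer == "lower":
        rate = rate * params.lower_layer_attenuation
    elif layer != "upper":
        raise ConfigError(f"unknown layer {layer!r}")
    return rate


@dataclass
class BackgroundRateState:
    """Latent (unrectified) shared background rate [Hz]."""

    rate: float
    params: BackgroundParams

    @property
    def spiking_rate(self) -> float:
        """Rate used for spike generation (rectified at zero)."""
        return max(self.rate, 0.0)


def ou_stationary_sd(params: BackgroundParams) -> float:
    """Stationary SD of the background rate; the table's volatility is
    interpreted as exactly this quantity."""
    return params.volatility


def ou_rate_step(state: BackgroundRateState, dt: float,
                 gaussian_draw: float) -> BackgroundRateState:
    """Exact-discretization OU update over ``dt`` [ms]."""
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    p = state.params
    decay = math.exp(-dt / p.filter_time)
    sd = ou_stationary_sd(p) * math.sqrt(1.0 - decay * decay)
    new = p.mean_rate + (state.rate - p.mean_rate) * decay + sd * gaussian_draw
    return BackgroundRateState(rate=new, params=p)


def generate_input_spikes(rate_trace, dt: float, rng: np.random.Generator,
                          mode: str = "poisson"):
    """Event times [ms] for a rate trace [Hz] sampled every ``dt`` ms.

    ``poisson`` draws a Poisson count per step (exact for piecewise-constant
    rates); ``bernoulli`` thins with probability rate*dt and warns when that
    probability exceeds 0.2, where thinning visibly undercounts.
    """
    rate = np.maximum(np.asarray(rate_trace, dtype=float), 0.0)
    mean = rate * dt * 1e-3  # Hz * ms
    if mode == "bernoulli":
        if np.any(mean > 0.2):
            warnings.warn("rate*dt exceeds 0.2; Bernoulli thinning undercounts "
                          "(use mode='poisson')", stacklevel=2)
        hits = np.nonzero(rng.random(mean.shape) < mean)[0]
        return hits * dt
    if mode != "poisson":
        raise ConfigError(f"unknown mode {mode!r}")
    counts = rng.poisson(mean)
    events = np.repeat(np.arange(counts.size), counts) * dt
    return events.astype(float)
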