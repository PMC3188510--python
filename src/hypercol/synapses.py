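"""Conductance-based synapses: unit-peak double-exponential kernels.

A presynaptic spike arriving (after its latency) at time 0 contributes the
conductance waveform

    s(t) = N * (exp(-t/tau_decay) - exp(-t/tau_rise)),   t >= 0,

with N chosen so that max_t s(t) = 1; the synaptic current is
``g * s(t) * (E_syn - V)``.  The waveform is realized as two exponential
state variables (one per time constant) that are both incremented by N at
each arrival and decay independently -- identical to summing kernels, O(1)
per spike.  NMDA carries no voltage-dependent block; it is a slow AMPA-like
class.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .config import ConfigError, NeuronParams, SynapseClassParams
from . import neurons as _neurons

__all__ = [
    "kernel_normalization",
    "kernel_peak_time",
    "kernel_value",
    "synaptic_current",
    "SynapticState",
    "step_synaptic_state",
    "psp_peak",
    "calibrate_gaba_reversal",
]


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum [ms]."""
    _check(tau_rise, tau_decay)
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)


def kernel_normalization(tau_rise: float, tau_decay: float) -> float:
    """Constant N normalizing the kernel peak to one."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def _check(tau_rise: float, tau_decay: float) -> None:
    if not 0 < tau_rise < tau_decay:
        raise ConfigError(f"require 0 < tau_rise < tau_decay "
                          f"(got {tau_rise}, {tau_decay})")


def kernel_value(t_since_arrival, tau_rise: float, tau_decay: float):
    """Unit-peak kernel value; zero before arrival."""
    n = kernel_normalization(tau_rise, tau_decay)
    t = np.asarray(t_since_arrival, dtype=float)
    out = n * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))
    return np.where(t < 0.0, 0.0, out)


def synaptic_current(v, params: SynapseClassParams, activation):
    """Current [nA] for membrane potential ``v`` [mV] and dimensionless
    activation (kernel superposition value)."""
    activation = np.asarray(activation, dtype=float)
    if np.any(activation < 0):
        raise ConfigError("activation must be >= 0")
    return params.peak_conductance * activation * (params.reversal - np.asarray(v)) * 1e-3


@dataclass
class SynapticState:
    """Two-exponential realization of one synapse class on one neuron (or an
    array of neurons).  ``decay_component - rise_component`` times the peak
    conductance is the instantaneous conductance."""

    tau_rise: float
    tau_decay: float
    decay_component: np.ndarray = field(default_factory=lambda: np.zeros(1))
    rise_component: np.ndarray = field(default_factory=lambda: np.zeros(1))
    pending: list = field(default_factory=list)  # (arrival_time, increment)
    time: float = 0.0

    @property
    def activation(self) -> np.ndarray:
        return self.decay_component - self.rise_component

    def schedule(self, arrival_time: float, increment: float = 1.0) -> None:
        self.pending.append((arrival_time, increment))
        self.pending.sort()


def step_synaptic_state(state: SynapticState, dt: float) -> SynapticState:
    """Advance by ``dt`` [ms]: exact exponential decay plus application of any
    queued arrivals, each decayed from its own arrival time to the step end
    (sub-step timing error bounded by the queue resolution, not dt)."""
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    t_end = state.time + dt
    n = kernel_normalization(state.tau_rise, state.tau_decay)
    state.decay_component = state.decay_component * math.exp(-dt / state.tau_decay)
    state.rise_component = state.rise_component * math.exp(-dt / state.tau_rise)
    remaining = []
    for t_arr, inc in state.pending:
        if t_arr <= t_end:
            age = t_end - t_arr
            state.decay_component = state.decay_component + inc * n * math.exp(-age / state.tau_decay)
            state.rise_component = state.rise_component + inc * n * math.exp(-age / state.tau_rise)
        else:
            remaining.append((t_arr, inc))
    state.pending = remaining
    state.time = t_end
    return state


# --------------------------------------------------------------------------
# PSP calibration against the published single-event amplitudes
# --------------------------------------------------------------------------

def psp_peak(neuron: NeuronParams, synapse: SynapseClassParams,
             dt: float = 0.02, horizon: float | None = None) -> float:
    """Absolute peak deflection of V from rest [mV] caused by one synaptic
    event delivered to a neuron at rest."""
    if synapse.peak_conductance == 0.0:
        return 0.0
    horizon = horizon or max(12.0 * synapse.tau_decay, 60.0)
    v_rest = _neurons.resting_potential(neuron)
    g = lambda t: synapse.peak_conductance * kernel_value(t - 1.0, synapse.tau_rise,
                                                          synapse.tau_decay)
    _, v, _ = _neurons.integrate_single_neuron(
        neuron, None, duration=horizon, dt=dt,
        conductances=[(g, synapse.reversal)], v0=v_rest)
    return float(np.max(np.abs(v - v_rest)))


def calibrate_gaba_reversal(neurons_by_kind, synapse_classes,
                            bounds=(-90.0, -60.0)) -> float:
    """One-time calibration of the (unpublished) GABA reversal potential.

    Minimizes the summed squared error between simulated single-event IPSP
    amplitudes and the published values for the GABA classes; returns the
    fitted reversal [mV].
    """
    gaba = {k: sc for k, sc in synapse_classes.items()
            if sc.name == "GABA" and sc.reference_psp is not None}
    if not gaba:
        raise ConfigError("no GABA classes with reference PSPs to calibrate")

    def loss(e_rev: float) -> float:
        err = 0.0
        for sc in gaba.values():
            trial = SynapseClassParams(sc.name, sc.target_kind, sc.tau_rise,
                                       sc.tau_decay, sc.peak_conductance,
                                       e_rev, sc.reference_psp)
            err += (psp_peak(neurons_by_kind[sc.target_kind], trial, dt=0.05)
                    - sc.reference_psp) ** 2
        return err

    res = minimize_scalar(loss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)
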