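"""Exponential integrate-and-fire membrane dynamics.

The membrane obeys

    dV/dt = (E_L - V + psi(V)) / tau_m(t) + I_syn / C,
    psi(V) = delta_t * exp((V - V_T(t)) / delta_t(t)),

with spike emission identified with the finite-time divergence of V.  After a
spike an excitatory cell's effective threshold, slope factor and inverse time
constant acquire additive offsets that relax exponentially back to baseline
("soft" refractoriness); inhibitory cells are simply clamped for a hard
refractory period.  Numerical integration stops at a finite cutoff voltage
where the exponential term dominates, and the residual time to divergence is
added analytically.

Functions here are pure and vectorize over numpy arrays; the network
simulator keeps its own state arrays and calls into them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .config import ConfigError, NeuronParams, RefractoryParams

__all__ = [
    "NeuronState",
    "spike_nonlinearity",
    "membrane_rhs",
    "resting_potential",
    "post_spike_update",
    "time_to_divergence",
    "integrate_single_neuron",
]

# cap on the exponent of psi to keep intermediate RK stages finite; any V this
# far above threshold is far beyond the cutoff anyway
_EXP_CAP = 30.0


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state of one neuron (scalar fields, mV / ms units)."""

    v: float
    inv_tau_m: float
    v_threshold: float
    delta_t: float
    time_since_spike: float = math.inf
    refractory_until: float = -math.inf

    @classmethod
    def at_rest(cls, params: NeuronParams) -> "NeuronState":
        return cls(v=resting_potential(params),
                   inv_tau_m=1.0 / params.tau_m,
                   v_threshold=params.v_threshold,
                   delta_t=params.delta_t)


def spike_nonlinearity(v, v_threshold, delta_t):
    """Spike-initiation term psi(V) = delta_t * exp((V - V_T)/delta_t) [mV]."""
    v = np.asarray(v, dtype=float)
    arg = np.minimum((v - v_threshold) / delta_t, _EXP_CAP)
    return delta_t * np.exp(arg)


def membrane_rhs(state: NeuronState, i_syn: float, params: NeuronParams) -> float:
    """dV/dt [mV/ms] for synaptic current ``i_syn`` [nA], using the state's
    instantaneous effective parameters."""
    psi = spike_nonlinearity(state.v, state.v_threshold, state.delta_t)
    return float(state.inv_tau_m * (params.e_leak - state.v + psi)
                 + i_syn / params.capacitance)


def resting_potential(params: NeuronParams, tol: float = 1e-9) -> float:
    """Stable (lower) root of E_L - V + psi(V) = 0.

    For the published parameters this sits within microvolts of E_L because
    psi is tiny there; it ceases to exist when E_L is pushed toward threshold.
    """
    f = lambda v: params.e_leak - v + float(
        spike_nonlinearity(v, params.v_threshold, params.delta_t))
    lo = params.e_leak - 20.0 * params.delta_t
    # the stable root lies below the unstable one; bracket up to the local max
    # of the rhs, i.e. where d/dV (= -1 + psi'/1) changes sign: psi'(V)=1
    v_knee = params.v_threshold  # psi'(V_T) = 1 exactly
    if f(v_knee) >= 0.0:
        raise ConfigError("no sub-threshold resting point for these parameters")
    return float(brentq(f, lo, v_knee, xtol=tol))


def post_spike_update(state: NeuronState, refractory: RefractoryParams,
                      params: NeuronParams, spike_time: float) -> NeuronState:
    """State immediately after a spike.

    Soft mode: V resets and the effective parameters acquire the configured
    offsets (offsets from a previous spike are overwritten, not summed).
    Hard mode: V resets and integration is suspended for the refractory
    period.
    """
    if refractory.mode == "hard":
        return replace(state, v=params.reset, time_since_spike=0.0,
                       refractory_until=spike_time + refractory.refractory_period)
    jumps = {"v_threshold": 0.0, "delta_t": 0.0, "inv_tau_m": 0.0}
    for comp in refractory.components:
        jumps[comp.target] += comp.amplitude
    return replace(state,
                   v=params.reset,
                   v_threshold=params.v_threshold + jumps["v_threshold"],
                   delta_t=params.delta_t + jumps["delta_t"],
                   inv_tau_m=1.0 / params.tau_m + jumps["inv_tau_m"],
                   time_since_spike=0.0)


def relax_soft_state(state: NeuronState, refractory: RefractoryParams,
                     params: NeuronParams, dt: float) -> NeuronState:
    """Advance the post-spike offsets by ``dt`` (exponential decay toward
    baseline); V itself is untouched."""
    if refractory.mode != "soft" or not math.isfinite(state.time_since_spike):
        return replace(state, time_since_spike=state.time_since_spike + dt)
    t = state.time_since_spike + dt
    off = {"v_threshold": 0.0, "delta_t": 0.0, "inv_tau_m": 0.0}
    for comp in refractory.components:
        off[comp.target] += comp.amplitude * math.exp(-t / comp.tau)
    return replace(state,
                   v_threshold=params.v_threshold + off["v_threshold"],
                   delta_t=params.delta_t + off["delta_t"],
                   inv_tau_m=1.0 / params.tau_m + off["inv_tau_m"],
                   time_since_spike=t)


def time_to_divergence(v_now, v_threshold, delta_t, tau_m):
    """Remaining time [ms] before the divergence of V, neglecting leak and
    synaptic currents: integrate dV/dt = psi(V)/tau_m from ``v_now`` to
    infinity, giving tau_m * exp(-(v_now - V_T)/delta_t)."""
    v_now = np.asarray(v_now, dtype=float)
    return tau_m * np.exp(-np.minimum((v_now - v_threshold) / delta_t, _EXP_CAP))


# --------------------------------------------------------------------------
# single-neuron reference integrator (PSP calibration, oracle tests)
# --------------------------------------------------------------------------

def integrate_single_neuron(params: NeuronParams,
                            refractory: RefractoryParams | None,
                            duration: float,
                            dt: float = 0.02,
                            current=None,
                            conductances=(),
                            v0: float | None = None,
                            cutoff_refine: int = 16):
    """Fixed-step RK4 integration of one neuron with the cutoff-and-
    extrapolate spike scheme.

    ``current`` is an optional callable t -> nA of injected current.
    ``conductances`` is a sequence of (g_of_t, reversal_mV) pairs; each
    ``g_of_t`` maps a time array [ms] to conductance [nS].  Returns
    ``(times, voltages, spike_times)``; voltages are sampled at step starts
    and hold the reset value while refractory.
    """
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps) * dt
    v = resting_potential(params) if v0 is None else float(v0)
    inv_tau = 1.0 / params.tau_m
    vt, dlt = params.v_threshold, params.delta_t
    soft = refractory is not None and refractory.mode == "soft"
    hard = refractory is not None and refractory.mode == "hard"
    t_last_spike = -math.inf
    refr_until = -math.inf
    out = np.empty(n_steps)
    spikes: list[float] = []

    def effective(t):
        if not soft or not math.isfinite(t_last_spike):
            return inv_tau, vt, dlt
        e_inv, e_vt, e_dl = inv_tau, vt, dlt
        age = t - t_last_spike
        for comp in refractory.components:  # type: ignore[union-attr]
            dec = comp.amplitude * math.exp(-age / comp.tau)
            if comp.target == "v_threshold":
                e_vt += dec
            elif comp.target == "delta_t":
                e_dl += dec
            else:
                e_inv += dec
        return e_inv, e_vt, e_dl

    def rhs(t, vv):
        e_inv, e_vt, e_dl = effective(t)
        arg = min((vv - e_vt) / e_dl, _EXP_CAP)
        i_syn = 0.0 if current is None else current(t)
        for g_of_t, e_rev in conductances:
            i_syn += float(g_of_t(np.array([t]))[0]) * (e_rev - vv) * 1e-3  # nS*mV -> nA
        return e_inv * (params.e_leak - vv + e_dl * math.exp(arg)) + i_syn / params.capacitance

    def rk4(t, vv, h):
        k1 = rhs(t, vv)
        k2 = rhs(t + 0.5 * h, vv + 0.5 * h * k1)
        k3 = rhs(t + 0.5 * h, vv + 0.5 * h * k2)
        k4 = rhs(t + h, vv + h * k3)
        return vv + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    for k in range(n_steps):
        t = times[k]
        out[k] = v
        if hard and t < refr_until:
            continue
        e_inv, e_vt, e_dl = effective(t)
        v_cut = e_vt + params.cutoff_margin * e_dl
        v_new = rk4(t, v, dt)
        if v_new >= v_cut or not math.isfinite(v_new):
            # refine the crossing within the step, then extrapolate
            h = dt / cutoff_refine
            vv, tc = v, t
            for j in range(cutoff_refine):
                vv_next = rk4(t + j * h, vv, h)
                if vv_next >= v_cut or not math.isfinite(vv_next):
                    vv, tc = (vv_next if math.isfinite(vv_next) else v_cut), t + (j + 1) * h
                    break
                vv = vv_next
            else:
                tc, vv = t + dt, vv
            t_sp = tc + float(time_to_divergence(vv, e_vt, e_dl, 1.0 / e_inv))
            spikes.append(t_sp)
            v = params.reset
            if soft:
                t_last_spike = t_sp
            if hard:
                refr_until = t_sp + refractory.refractory_period  # type: ignore[union-attr]
        else:
            v = v_new
    return times, out, np.asarray(spikes)
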