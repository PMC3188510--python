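"""Model configuration for the two-layer V1 hypercolumn.

All parameters of the model live here as frozen dataclasses with the published
table values as defaults: single-neuron EIF parameters, post-spike
refractoriness, synaptic kinetics and efficacies, connection-probability
profiles and latencies, LGN drive, and the shared Ornstein-Uhlenbeck
background.  Units follow the tables throughout: ms, nF, mV, nS, Hz, degrees.
No silent unit conversion happens anywhere.

The module also owns network-size scaling.  Connection probabilities and peak
conductances are defined at the reference size (N_E = 4000, N_I = 1000 per
layer); for any other size they are rescaled so that both the spatial mean and
the quenched (across-neuron) variance of the time-averaged recurrent synaptic
conductance are preserved.  The rest of the package never sees raw
probabilities: it asks a ``NetworkSpec`` for the effective profile of a
pathway at the spec's own size.
"""
from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "NeuronParams",
    "RefractoryComponent",
    "RefractoryParams",
    "SynapseClassParams",
    "PathwaySpec",
    "LGNParams",
    "BackgroundParams",
    "NetworkSpec",
    "default_spec",
    "load_spec",
    "save_spec",
    "spec_to_dict",
    "spec_from_dict",
    "scale_network",
    "spec_hash",
    "list_presets",
    "load_preset",
]

Layer = Literal["upper", "lower"]
Kind = Literal["E", "I"]

REF_N_EXC = 4000
REF_N_INH = 1000


class ConfigError(ValueError):
    """Raised when a configuration document or parameter set is invalid."""


# --------------------------------------------------------------------------
# parameter blocks (table defaults)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Exponential integrate-and-fire membrane parameters for one population.

    ``tau_m`` [ms], ``capacitance`` [nF], ``e_leak``/``v_threshold``/
    ``delta_t``/``v_reset``/``v_cutoff`` [mV].  ``v_cutoff`` is the voltage at
    which integration stops and the analytic divergence-time extrapolation
    takes over; the default ``v_threshold + 10 delta_t`` makes the exponential
    term dominate the leak there by far more than a factor of ten.
    """

    kind: Kind
    tau_m: float
    capacitance: float
    e_leak: float = -57.8
    v_threshold: float = -45.2
    delta_t: float = 1.2
    v_reset: float | None = None  # default: e_leak
    v_cutoff: float | None = None  # default: v_threshold + 10*delta_t

    @property
    def reset(self) -> float:
        return self.e_leak if self.v_reset is None else self.v_reset

    @property
    def cutoff(self) -> float:
        if self.v_cutoff is None:
            return self.v_threshold + 10.0 * self.delta_t
        return self.v_cutoff

    @property
    def cutoff_margin(self) -> float:
        """Cutoff expressed in units of delta_t above threshold."""
        return (self.cutoff - self.v_threshold) / self.delta_t

    def validate(self) -> None:
        if self.tau_m <= 0:
            raise ConfigError(f"neuron[{self.kind}].tau_m must be > 0")
        if self.capacitance <= 0:
            raise ConfigError(f"neuron[{self.kind}].capacitance must be > 0")
        if self.delta_t <= 0:
            raise ConfigError(f"neuron[{self.kind}].delta_t must be > 0")
        if self.reset >= self.cutoff:
            raise ConfigError(f"neuron[{self.kind}].v_reset must be below v_cutoff")
        # the exponential term must dominate the leak at the cutoff,
        # otherwise the analytic spike-time extrapolation is invalid
        psi = self.delta_t * math.exp((self.cutoff - self.v_threshold) / self.delta_t)
        leak = abs(self.e_leak - self.cutoff)
        if psi < 10.0 * leak:
            raise ConfigError(
                f"neuron[{self.kind}].v_cutoff={self.cutoff:g} mV: exponential term "
                f"({psi:.3g} mV) does not dominate the leak ({leak:.3g} mV) tenfold"
            )


@dataclass(frozen=True)
class RefractoryComponent:
    """One additive post-spike offset: ``target`` jumps by ``amplitude``
    immediately after a spike and relaxes back exponentially with time
    constant ``tau`` [ms]."""

    target: Literal["v_threshold", "delta_t", "inv_tau_m"]
    amplitude: float  # mV for voltage-like targets, 1/ms for inv_tau_m
    tau: float

    def validate(self) -> None:
        if self.tau <= 0:
            raise ConfigError(f"refractory component on {self.target}: tau must be > 0")


@dataclass(frozen=True)
class RefractoryParams:
    """Post-spike handling: soft (excitatory) or hard (inhibitory)."""

    mode: Literal["soft", "hard"]
    components: tuple[RefractoryComponent, ...] = ()
    refractory_period: float = 2.0  # ms, hard mode only

    def validate(self, kind: Kind) -> None:
        if self.mode == "soft" and kind != "E":
            raise ConfigError("soft refractoriness is reserved for excitatory cells")
        if self.mode == "hard" and kind != "I":
            raise ConfigError("hard refractoriness is reserved for inhibitory cells")
        if self.mode == "hard" and self.refractory_period <= 0:
            raise ConfigError("refractory_period must be > 0")
        for c in self.components:
            c.validate()


# Post-spike relaxation of the excitatory EIF: the spike threshold acquires
# two decaying offsets, the slope factor and the inverse membrane time
# constant one each.  Offsets are reset (not summed) on successive spikes.
SOFT_REFRACTORY_DEFAULT = RefractoryParams(
    mode="soft",
    components=(
        RefractoryComponent("v_threshold", 22.9, 14.7),
        RefractoryComponent("v_threshold", 13.5, 76.2),
        RefractoryComponent("delta_t", 10.0, 17.7),
        RefractoryComponent("inv_tau_m", 0.14, 14.3),
    ),
)

HARD_REFRACTORY_DEFAULT = RefractoryParams(mode="hard", refractory_period=2.0)


@dataclass(frozen=True)
class SynapseClassParams:
    """Kinetics and efficacy of one synapse class onto one target population.

    ``tau_rise`` < ``tau_decay`` [ms]; ``peak_conductance`` [nS] is the
    reference-size value (rescaled per pathway for other sizes);
    ``reference_psp`` [mV] is the published single-event PSP used for
    calibration checks.
    """

    name: Literal["AMPA", "NMDA", "GABA"]
    target_kind: Kind
    tau_rise: float
    tau_decay: float
    peak_conductance: float
    reversal: float
    reference_psp: float | None = None

    def validate(self) -> None:
        tag = f"synapse[{self.name} on {self.target_kind}]"
        if not 0 < self.tau_rise < self.tau_decay:
            raise ConfigError(f"{tag}: require 0 < tau_rise < tau_decay "
                              f"(got rise={self.tau_rise}, decay={self.tau_decay})")
        if self.peak_conductance < 0:
            raise ConfigError(f"{tag}: peak_conductance must be >= 0")
        if self.name in ("AMPA", "NMDA") and self.reversal <= -57.8:
            raise ConfigError(f"{tag}: excitatory reversal must exceed the leak potential")
        if self.name == "GABA" and self.reversal >= -57.8:
            raise ConfigError(f"{tag}: inhibitory reversal must be below the leak potential")


def _default_synapse_classes(e_gaba: float = -75.0) -> dict[str, SynapseClassParams]:
    """Synaptic kinetics/efficacies, keyed ``"<class>:<target kind>"``.

    The GABA reversal is not published; -75 mV is the value the one-time
    PSP calibration returns (it reproduces both printed IPSP amplitudes to
    within 1%, where -70 mV misses them by ~30%).
    """
    mk = SynapseClassParams
    return {
        "AMPA:E": mk("AMPA", "E", 1.0, 3.0, 1.0, 0.0, 0.84),
        "AMPA:I": mk("AMPA", "I", 1.0, 3.0, 1.5, 0.0, 2.07),
        "GABA:E": mk("GABA", "E", 1.0, 4.0, 4.0, e_gaba, 1.13),
        "GABA:I": mk("GABA", "I", 1.0, 2.0, 4.0, e_gaba, 1.36),
        "NMDA:E": mk("NMDA", "E", 3.0, 80.0, 0.14, 0.0, 0.50),
        # the efficacy table defines no NMDA class onto interneurons:
        # excitatory spikes evoke composite AMPA+NMDA responses in excitatory
        # targets but AMPA-only responses in inhibitory targets
        "NMDA:I": mk("NMDA", "I", 3.0, 80.0, 0.0, 0.0, None),
    }


@dataclass(frozen=True)
class PathwaySpec:
    """One synaptic pathway between populations.

    ``p0`` is the ring-averaged connection probability at the reference size,
    ``p1`` the amplitude of its cosine spatial modulation (orientation
    periodicity, cos 2Δθ).  ``latency`` [ms].  ``interlayer`` pathways are
    subject to the coupling scale Γ.
    """

    source_layer: Layer
    source_kind: Kind
    target_layer: Layer
    target_kind: Kind
    p0: float
    p1: float
    latency: float
    interlayer: bool

    @property
    def name(self) -> str:
        return (f"{self.source_layer}{self.source_kind}->"
                f"{self.target_layer}{self.target_kind}")

    def validate(self) -> None:
        if self.p0 < 0:
            raise ConfigError(f"pathway {self.name}: p0 must be >= 0")
        if self.latency <= 0:
            raise ConfigError(f"pathway {self.name}: latency must be > 0")
        if self.interlayer != (self.source_layer != self.target_layer):
            raise ConfigError(f"pathway {self.name}: interlayer flag inconsistent")
        # peak of the mean-normalized rectified profile must be a probability
        if peak_profile_value(self.p0, self.p1) > 1.0 + 1e-12:
            raise ConfigError(
                f"pathway {self.name}: profile peak exceeds 1 at reference size")


def _default_pathways() -> tuple[PathwaySpec, ...]:
    """Connection-probability table: intra-layer rows identical per layer,
    inter-layer rows as published (inhibitory inter-layer rows symmetric)."""
    rows: list[PathwaySpec] = []
    for layer in ("upper", "lower"):
        for tk in ("E", "I"):
            rows.append(PathwaySpec(layer, "E", layer, tk, 0.06, 0.06, 1.0, False))
            rows.append(PathwaySpec(layer, "I", layer, tk, 0.24, 0.12, 1.0, False))
    # upper excitatory -> lower layer
    for tk in ("E", "I"):
        rows.append(PathwaySpec("upper", "E", "lower", tk, 0.06, 0.18, 3.0, True))
    # lower excitatory -> upper layer (distinct parameters per target kind)
    rows.append(PathwaySpec("lower", "E", "upper", "E", 0.06, 0.18, 1.0, True))
    rows.append(PathwaySpec("lower", "E", "upper", "I", 0.07, 0.16, 1.0, True))
    # inter-layer inhibition, both directions, unmodulated
    for tk in ("E", "I"):
        rows.append(PathwaySpec("upper", "I", "lower", tk, 0.12, 0.0, 3.0, True))
        rows.append(PathwaySpec("lower", "I", "upper", tk, 0.12, 0.0, 1.0, True))
    return tuple(rows)


@dataclass(frozen=True)
class LGNParams:
    """Feed-forward drive: orientation/contrast-tuned Poisson input.

    The single-afferent rate grows logarithmically with contrast from
    ``dark_rate`` (5 Hz) to ``max_rate`` (48 Hz); the population rate seen by
    a cortical cell is ``rate_offset + rate_gain * n(C) * tuning`` [Hz], with
    n(C) the normalized contrast response.  ``contrast_log_scale`` sets the
    curvature of the logarithmic contrast mapping (half saturation near 9%
    contrast for the default 100).  The lower layer receives the rate scaled
    by ``lower_layer_attenuation``.
    """

    g_lgn: float = 1.0  # nS, AMPA-type
    rate_offset: float = 150.0  # Hz, untuned dark component
    rate_gain: float = 2850.0  # Hz, tuned component at full contrast
    dark_rate: float = 5.0  # Hz, single afferent in the dark
    max_rate: float = 48.0  # Hz, single afferent at full contrast
    tuning_broadness: float = 1.0  # epsilon in [0, 1]
    lower_layer_attenuation: float = 0.5
    inhibitory_attenuation: float = 1.0  # LGN rate factor onto interneurons
    contrast_log_scale: float = 100.0

    def validate(self) -> None:
        for f in ("g_lgn", "rate_offset", "rate_gain", "dark_rate", "max_rate"):
            if getattr(self, f) < 0:
                raise ConfigError(f"lgn.{f} must be >= 0")
        if not 0.0 <= self.tuning_broadness <= 1.0:
            raise ConfigError("lgn.tuning_broadness must lie in [0, 1]")
        if not 0.0 < self.lower_layer_attenuation <= 1.0:
            raise ConfigError("lgn.lower_layer_attenuation must lie in (0, 1]")
        if not 0.0 < self.inhibitory_attenuation <= 1.0:
            raise ConfigError("lgn.inhibitory_attenuation must lie in (0, 1]")
        if self.contrast_log_scale <= 0:
            raise ConfigError("lgn.contrast_log_scale must be > 0")


@dataclass(frozen=True)
class BackgroundParams:
    """Shared-rate Ornstein-Uhlenbeck background drive.

    ``volatility`` is the stationary standard deviation of the rate [Hz].
    """

    g_bg: float = 10.0  # nS, AMPA-type
    mean_rate: float = 10.0  # Hz
    volatility: float = 1.0  # Hz (stationary SD)
    filter_time: float = 10.0  # ms

    def validate(self) -> None:
        if self.mean_rate <= 0:
            raise ConfigError("background.mean_rate must be > 0")
        if self.filter_time <= 0:
            raise ConfigError("background.filter_time must be > 0")
        if self.volatility < 0:
            raise ConfigError("background.volatility must be >= 0")


# --------------------------------------------------------------------------
# connection-probability profile helpers (mean-normalized rectified cosine)
# --------------------------------------------------------------------------

def _rectified_cosine_mean(beta: float) -> float:
    """Ring average of [1 + beta*cos(u)]_+ over u in [-pi, pi)."""
    if beta <= 1.0:
        return 1.0
    u0 = math.acos(-1.0 / beta)
    return (u0 + beta * math.sin(u0)) / math.pi


def _rectified_cosine_sq_mean(beta: float) -> float:
    """Ring average of [1 + beta*cos(u)]_+^2."""
    if beta <= 1.0:
        return 1.0 + 0.5 * beta * beta
    u0 = math.acos(-1.0 / beta)
    s, s2 = math.sin(u0), math.sin(2.0 * u0)
    return (u0 * (1.0 + 0.5 * beta * beta) + 2.0 * beta * s + 0.25 * beta * beta * s2) / math.pi


def profile_shape(dtheta_deg, beta: float):
    """Unit-mean angular shape of a connection profile at modulation ratio
    ``beta = p1/p0``: [1 + beta*cos(2Δθ)]_+ normalized to ring average 1."""
    u = np.deg2rad(2.0 * np.asarray(dtheta_deg, dtype=float))
    raw = np.maximum(1.0 + beta * np.cos(u), 0.0)
    return raw / _rectified_cosine_mean(beta)


def peak_profile_value(p0: float, p1: float) -> float:
    """Maximum of the mean-normalized profile p0*shape(Δθ)."""
    if p0 == 0.0:
        return 0.0
    beta = p1 / p0
    if beta < 0:
        raise ConfigError("negative modulation p1 not supported")
    return p0 * (1.0 + beta) / _rectified_cosine_mean(beta)


def profile_sq_mean(p0: float, p1: float) -> float:
    """Ring average of the squared profile (needed by the size scaling)."""
    if p0 == 0.0:
        return 0.0
    beta = p1 / p0
    return p0 * p0 * _rectified_cosine_sq_mean(beta) / _rectified_cosine_mean(beta) ** 2


# --------------------------------------------------------------------------
# the complete network specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Full parameterization of one hypercolumn instance.

    Sizes are per layer; the network holds ``2*(n_exc + n_inh)`` neurons.
    Probabilities and conductances given in the parameter blocks refer to the
    reference size; effective values at (``n_exc``, ``n_inh``) come from
    :meth:`pathway_probability_scale` / :meth:`pathway_conductance_scale`.
    """

    n_exc: int = REF_N_EXC
    n_inh: int = REF_N_INH
    neurons: Mapping[str, NeuronParams] = field(default_factory=lambda: {
        "E": NeuronParams("E", 23.30, 0.26),
        "I": NeuronParams("I", 11.65, 0.13),
    })
    refractory: Mapping[str, RefractoryParams] = field(default_factory=lambda: {
        "E": SOFT_REFRACTORY_DEFAULT,
        "I": HARD_REFRACTORY_DEFAULT,
    })
    synapse_classes: Mapping[str, SynapseClassParams] = field(
        default_factory=_default_synapse_classes)
    pathways: tuple[PathwaySpec, ...] = field(default_factory=_default_pathways)
    lgn: LGNParams = field(default_factory=LGNParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    interlayer_scale: float = 1.0  # Γ
    gamma_scope: Literal["both", "lower_to_upper"] = "both"
    integration_step: float = 0.2  # ms
    master_seed: int = 0
    ref_n_exc: int = REF_N_EXC
    ref_n_inh: int = REF_N_INH
    size_scaling: Literal["preserve", "none"] = "preserve"
    probability_overflow: Literal["error", "clip"] = "error"

    # -- validation --------------------------------------------------------
    def validate(self) -> "NetworkSpec":
        if self.n_exc < 1 or self.n_inh < 1:
            raise ConfigError("population sizes must be >= 1")
        if self.ref_n_exc < 1 or self.ref_n_inh < 1:
            raise ConfigError("reference sizes must be >= 1")
        if not 0.0 <= self.interlayer_scale <= 1.0:
            raise ConfigError("interlayer_scale (Γ) must lie in [0, 1]")
        if self.integration_step <= 0:
            raise ConfigError("integration_step must be > 0")
        for kind in ("E", "I"):
            self.neurons[kind].validate()
            self.refractory[kind].validate(kind)  # type: ignore[arg-type]
        for sc in self.synapse_classes.values():
            sc.validate()
        for pw in self.pathways:
            pw.validate()
            # effective (scaled) profile must stay a probability in strict mode
            if self.probability_overflow == "error":
                s = self.pathway_probability_scale(pw)
                if s * peak_profile_value(pw.p0, pw.p1) > 1.0 + 1e-9:
                    raise ConfigError(
                        f"pathway {pw.name}: scaled profile peak "
                        f"{s * peak_profile_value(pw.p0, pw.p1):.3f} exceeds 1 at size "
                        f"(n_exc={self.n_exc}, n_inh={self.n_inh}); use "
                        f"probability_overflow='clip' to allow saturation")
        return self

    # -- sizes -------------------------------------------------------------
    @property
    def n_total(self) -> int:
        return 2 * (self.n_exc + self.n_inh)

    def population_size(self, kind: Kind) -> int:
        return self.n_exc if kind == "E" else self.n_inh

    def ref_population_size(self, kind: Kind) -> int:
        return self.ref_n_exc if kind == "E" else self.ref_n_inh

    # -- size scaling ------------------------------------------------------
    def _size_ratio(self, pw: PathwaySpec) -> float:
        return self.population_size(pw.source_kind) / self.ref_population_size(pw.source_kind)

    def pathway_probability_scale(self, pw: PathwaySpec) -> float:
        """Multiplier on the reference probability profile of ``pw``.

        Chosen so that, together with :meth:`pathway_conductance_scale`, the
        spatial mean and the quenched spatial variance of the time-averaged
        synaptic conductance received from this pathway are both preserved
        relative to the reference network (exactly, for unclipped profiles).
        """
        if self.size_scaling == "none":
            return 1.0
        x = self._size_ratio(pw)
        if pw.p0 == 0.0:
            return 1.0
        pbar = pw.p0
        qbar = profile_sq_mean(pw.p0, pw.p1)
        return pbar / (x * (pbar - qbar) + qbar)

    def pathway_mean_probability(self, pw: PathwaySpec) -> float:
        """Ring-averaged effective connection probability (after clipping)."""
        s = self.pathway_probability_scale(pw)
        if s * peak_profile_value(pw.p0, pw.p1) <= 1.0 or pw.p0 == 0.0:
            return s * pw.p0
        # clipped profile: average min(s*p0*shape, 1) numerically
        grid = np.linspace(-90.0, 90.0, 3601, endpoint=False)
        prof = np.minimum(s * pw.p0 * profile_shape(grid, pw.p1 / pw.p0), 1.0)
        return float(prof.mean())

    def pathway_conductance_scale(self, pw: PathwaySpec) -> float:
        """Multiplier on the reference peak conductances of ``pw``.

        Preserves the mean conductance drive exactly: the product of expected
        in-degree and peak conductance equals its reference value.
        """
        if self.size_scaling == "none":
            return 1.0
        if pw.p0 == 0.0:
            return 1.0
        k_ref = pw.p0 * self.ref_population_size(pw.source_kind)
        k_now = self.pathway_mean_probability(pw) * self.population_size(pw.source_kind)
        return k_ref / k_now

    def pathway_gamma(self, pw: PathwaySpec) -> float:
        """Γ factor applied to this pathway's conductances."""
        if not pw.interlayer:
            return 1.0
        if self.gamma_scope == "lower_to_upper" and not (
                pw.source_layer == "lower" and pw.target_layer == "upper"):
            return 1.0
        return self.interlayer_scale

    def effective_profile(self, pw: PathwaySpec, dtheta_deg) -> np.ndarray:
        """Effective connection probability at angular distance(s) ``dtheta_deg``."""
        if pw.p0 == 0.0:
            return np.zeros_like(np.asarray(dtheta_deg, dtype=float))
        s = self.pathway_probability_scale(pw)
        prof = s * pw.p0 * profile_shape(dtheta_deg, pw.p1 / pw.p0)
        return np.minimum(prof, 1.0)


# --------------------------------------------------------------------------
# construction / scaling helpers
# --------------------------------------------------------------------------

def default_spec(n_exc: int = REF_N_EXC, n_inh: int = REF_N_INH, *,
                 n_total: int | None = None, **overrides) -> NetworkSpec:
    """Baseline spec, optionally at a scaled size.

    ``n_total`` picks sizes in the reference 4:1 excitatory/inhibitory ratio
    (``n_total = 2*(n_exc + n_inh)``).  Keyword overrides go straight to the
    :class:`NetworkSpec` constructor.
    """
    if n_total is not None:
        n_exc = int(round(n_total * 0.4))
        n_inh = int(round(n_total * 0.1))
    spec = NetworkSpec(n_exc=n_exc, n_inh=n_inh, **overrides)
    return spec.validate()


def scale_network(spec: NetworkSpec, n_exc: int, n_inh: int | None = None, *,
                  on_overflow: Literal["error", "clip"] | None = None) -> NetworkSpec:
    """Return ``spec`` at a different size with statistics-preserving scaling.

    Probabilities/conductances stay expressed at the reference size in the
    returned spec; the effective values follow the preservation rule relative
    to ``(spec.ref_n_exc, spec.ref_n_inh)``, so scaling is idempotent at the
    reference size and composes.
    """
    if n_inh is None:
        n_inh = max(1, int(round(n_exc * spec.ref_n_inh / spec.ref_n_exc)))
    if n_exc < 1 or n_inh < 1:
        raise ConfigError("target sizes must be >= 1")
    overflow = spec.probability_overflow if on_overflow is None else on_overflow
    out = replace(spec, n_exc=int(n_exc), n_inh=int(n_inh),
                  probability_overflow=overflow)
    return out.validate()


# --------------------------------------------------------------------------
# serialization (YAML round trip, unknown keys rejected)
# --------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _as_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def spec_to_dict(spec: NetworkSpec) -> dict:
    d = _as_dict(spec)
    d["schema_version"] = _SCHEMA_VERSION
    return d


def _build(cls, data: Mapping, context: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return data


def spec_from_dict(data: Mapping) -> NetworkSpec:
    data = dict(data)
    version = data.pop("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    _build(NetworkSpec, data, "spec")
    kwargs: dict = {}
    base = NetworkSpec()
    for key, value in data.items():
        if key == "neurons":
            kwargs[key] = {
                k: NeuronParams(**_build(NeuronParams, v, f"neurons.{k}"))
                for k, v in value.items()}
        elif key == "refractory":
            ref = {}
            for k, v in value.items():
                v = dict(_build(RefractoryParams, v, f"refractory.{k}"))
                v["components"] = tuple(
                    RefractoryComponent(**_build(RefractoryComponent, c, f"refractory.{k}"))
                    for c in v.get("components", ()))
                ref[k] = RefractoryParams(**v)
            kwargs[key] = ref
        elif key == "synapse_classes":
            kwargs[key] = {
                k: SynapseClassParams(**_build(SynapseClassParams, v, f"synapse_classes.{k}"))
                for k, v in value.items()}
        elif key == "pathways":
            kwargs[key] = tuple(
                PathwaySpec(**_build(PathwaySpec, v, "pathways[]")) for v in value)
        elif key == "lgn":
            kwargs[key] = LGNParams(**_build(LGNParams, value, "lgn"))
        elif key == "background":
            kwargs[key] = BackgroundParams(**_build(BackgroundParams, value, "background"))
        else:
            kwargs[key] = value
    spec = replace(base, **kwargs)
    return spec.validate()


def save_spec(spec: NetworkSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(source: str | Path | Mapping | None = None) -> NetworkSpec:
    """Load and validate a spec from a YAML file, a mapping, or nothing
    (all-defaults).  Unknown keys raise :class:`ConfigError`."""
    if source is None:
        return NetworkSpec().validate()
    if isinstance(source, Mapping):
        return spec_from_dict(source)
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return NetworkSpec().validate()
    if not isinstance(data, Mapping):
        raise ConfigError("configuration document must be a mapping")
    return spec_from_dict(data)


def spec_hash(spec: NetworkSpec) -> str:
    """Stable content hash of a spec (canonical YAML, sha256)."""
    canon = yaml.safe_dump(spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# shipped configuration presets
# --------------------------------------------------------------------------

def _presets_dir() -> Path:
    return Path(__file__).parent / "presets"


def list_presets() -> list[str]:
    return sorted(p.stem for p in _presets_dir().glob("*.yaml"))


def load_preset(name: str) -> NetworkSpec:
    path = _presets_dir() / f"{name}.yaml"
    if not path.exists():
        raise ConfigError(f"unknown preset {name!r}; available: {list_presets()}")
    return load_spec(path)
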