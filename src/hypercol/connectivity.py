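"""Quenched random wiring of the two-ring hypercolumn.

Neurons sit on a regular angular grid covering [-90, +90) degrees of
preferred orientation (orientation periodicity 180 deg) within each of the
four populations (upper/lower x excitatory/inhibitory).  The probability
that a presynaptic neuron contacts a postsynaptic one depends only on their
angular distance through a rectified-cosine profile whose ring average is
the pathway's p0; wiring is an independent Bernoulli draw per ordered pair
(no autapses).  Each connection carries the pathway latency and per-class
peak conductances, with inter-layer conductances pre-multiplied by the
coupling scale Gamma.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (ConfigError, NetworkSpec, PathwaySpec, peak_profile_value,
                     profile_shape)

__all__ = [
    "wrap_angle",
    "population_angles",
    "connection_probability",
    "expected_out_degree",
    "ConnectivityMatrix",
    "build_network",
    "apply_interlayer_scale",
    "compile_graphs",
]

POPULATIONS = (("upper", "E"), ("upper", "I"), ("lower", "E"), ("lower", "I"))


def wrap_angle(dtheta_deg):
    """Wrap an orientation difference into [-90, +90) degrees."""
    return (np.asarray(dtheta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def population_angles(n: int) -> np.ndarray:
    """Evenly spaced preferred orientations in [-90, +90) for ``n`` cells."""
    return -90.0 + 180.0 * np.arange(n) / n


def connection_probability(dtheta_deg, p0: float, p1: float):
    """Connection probability at angular distance ``dtheta_deg``.

    Rectified cosine profile with 180-deg periodicity, normalized so that its
    ring average equals ``p0`` (hence ``p1`` is the modulation amplitude of
    the unrectified cosine); this normalization is what makes the published
    mean target counts come out as p0 times the target population size even
    for strongly modulated pathways.
    """
    if p0 < 0:
        raise ConfigError("p0 must be >= 0")
    if p0 == 0.0:
        return np.zeros_like(np.asarray(dtheta_deg, dtype=float))
    if peak_profile_value(p0, p1) > 1.0 + 1e-12:
        raise ConfigError(f"profile (p0={p0}, p1={p1}) exceeds probability 1 at its peak")
    return p0 * profile_shape(dtheta_deg, p1 / p0)


def expected_out_degree(pathway: PathwaySpec, target_population_size: int,
                        spec: NetworkSpec | None = None) -> float:
    """Expected number of targets of one presynaptic cell of this pathway:
    target population size times the ring average of the (effective)
    profile.  Without a ``spec`` the reference-size profile is used, whose
    ring average is p0 by construction."""
    if spec is None:
        return pathway.p0 * target_population_size
    return spec.pathway_mean_probability(pathway) * target_population_size


@dataclass
class PathwayWiring:
    """Realized adjacency of one pathway (CSR over local source indices)."""

    pathway: PathwaySpec
    indptr: np.ndarray  # (n_src + 1,)
    targets: np.ndarray  # global postsynaptic indices, concatenated
    latency: float  # ms
    base_conductances: dict = field(default_factory=dict)  # class -> nS at Gamma=1
    conductances: dict = field(default_factory=dict)  # class -> nS after Gamma

    @property
    def n_connections(self) -> int:
        return int(self.targets.size)


@dataclass
class ConnectivityMatrix:
    """Complete quenched wiring of one network realization."""

    n_total: int
    offsets: dict  # (layer, kind) -> global index offset
    sizes: dict  # (layer, kind) -> population size
    angles: np.ndarray  # (n_total,) preferred orientation per neuron
    wirings: list  # list[PathwayWiring]
    gamma: float
    gamma_scope: str

    def wiring(self, name: str) -> PathwayWiring:
        for w in self.wirings:
            if w.pathway.name == name:
                return w
        raise KeyError(name)

    def content_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        # order-independent: pathways sorted by name so a round trip through
        # storage (which may reorder groups) hashes identically
        for w in sorted(self.wirings, key=lambda ww: ww.pathway.name):
            h.update(w.pathway.name.encode())
            h.update(w.indptr.tobytes())
            h.update(w.targets.tobytes())
        return h.hexdigest()[:16]


def _gamma_factor(spec_gamma: float, scope: str, pw: PathwaySpec) -> float:
    if not pw.interlayer:
        return 1.0
    if scope == "lower_to_upper" and not (pw.source_layer == "lower"
                                          and pw.target_layer == "upper"):
        return 1.0
    return spec_gamma


def build_network(spec: NetworkSpec, rng: np.random.Generator) -> ConnectivityMatrix:
    """Draw one wiring realization.  Deterministic for a given generator
    state; the same master seed reproduces the wiring bit for bit."""
    offsets, sizes, angle_list = {}, {}, []
    off = 0
    for layer, kind in POPULATIONS:
        n = spec.population_size(kind)
        offsets[(layer, kind)] = off
        sizes[(layer, kind)] = n
        angle_list.append(population_angles(n))
        off += n
    angles = np.concatenate(angle_list)
    wirings: list[PathwayWiring] = []
    for pw in spec.pathways:
        n_src = sizes[(pw.source_layer, pw.source_kind)]
        n_tgt = sizes[(pw.target_layer, pw.target_kind)]
        src_angles = population_angles(n_src)
        tgt_angles = population_angles(n_tgt)
        tgt_off = offsets[(pw.target_layer, pw.target_kind)]
        same_pop = (pw.source_layer == pw.target_layer
                    and pw.source_kind == pw.target_kind)
        indptr = np.zeros(n_src + 1, dtype=np.int64)
        chunks: list[np.ndarray] = []
        # chunked Bernoulli draws to bound memory at large sizes
        step = max(1, min(n_src, 8 * 1024 * 1024 // max(n_tgt, 1)))
        for lo in range(0, n_src, step):
            hi = min(lo + step, n_src)
            dth = wrap_angle(tgt_angles[None, :] - src_angles[lo:hi, None])
            prob = spec.effective_profile(pw, dth)
            hit = rng.random(prob.shape) < prob
            if same_pop:
                idx = np.arange(lo, hi)
                hit[np.arange(hi - lo), idx] = False  # no autapses
            for row in range(hi - lo):
                tg = np.nonzero(hit[row])[0]
                chunks.append(tg + tgt_off)
                indptr[lo + row + 1] = indptr[lo + row] + tg.size
        targets = (np.concatenate(chunks) if chunks
                   else np.empty(0, dtype=np.int64)).astype(np.int64)
        g_scale = spec.pathway_conductance_scale(pw)
        classes = ("AMPA", "NMDA") if pw.source_kind == "E" else ("GABA",)
        base = {}
        for cls in classes:
            key = f"{cls}:{pw.target_kind}"
            base[cls] = spec.synapse_classes[key].peak_conductance * g_scale
        gfac = _gamma_factor(spec.interlayer_scale, spec.gamma_scope, pw)
        wirings.append(PathwayWiring(
            pathway=pw, indptr=indptr, targets=targets, latency=pw.latency,
            base_conductances=base,
            conductances={c: g * gfac for c, g in base.items()}))
    return ConnectivityMatrix(n_total=spec.n_total, offsets=offsets, sizes=sizes,
                              angles=angles, wirings=wirings,
                              gamma=spec.interlayer_scale,
                              gamma_scope=spec.gamma_scope)


def apply_interlayer_scale(matrix: ConnectivityMatrix, gamma: float) -> ConnectivityMatrix:
    """Rescale inter-layer conductances to coupling ``gamma``, absolutely
    (relative to their Gamma=1 baseline); intra-layer pathways untouched."""
    if not 0.0 <= gamma <= 1.0:
        raise ConfigError("Gamma must lie in [0, 1]")
    for w in matrix.wirings:
        gfac = _gamma_factor(gamma, matrix.gamma_scope, w.pathway)
        w.conductances = {c: g * gfac for c, g in w.base_conductances.items()}
    matrix.gamma = gamma
    return matrix


def compile_graphs(matrix: ConnectivityMatrix) -> dict:
    """Flatten the per-pathway wiring into per-source-neuron CSR graphs the
    simulator can scatter from: one graph for excitatory sources (AMPA and
    NMDA weights) and one for inhibitory sources (GABA weights)."""
    n = matrix.n_total
    out = {}
    for src_kind, classes in (("E", ("AMPA", "NMDA")), ("I", ("GABA",))):
        src_ids, tgts, lats = [], [], []
        weights = {c: [] for c in classes}
        for w in matrix.wirings:
            if w.pathway.source_kind != src_kind or w.targets.size == 0:
                continue
            src_off = matrix.offsets[(w.pathway.source_layer, src_kind)]
            counts = np.diff(w.indptr)
            src_ids.append(np.repeat(np.arange(counts.size) + src_off, counts))
            tgts.append(w.targets)
            lats.append(np.full(w.targets.size, w.latency))
            for c in classes:
                weights[c].append(np.full(w.targets.size, w.conductances[c]))
        if src_ids:
            src = np.concatenate(src_ids)
            order = np.argsort(src, kind="stable")
            src = src[order]
            graph = {
                "targets": np.concatenate(tgts)[order],
                "latency": np.concatenate(lats)[order],
                "indptr": np.searchsorted(src, np.arange(n + 1)),
            }
            for c in classes:
                graph[f"w_{c.lower()}"] = np.concatenate(weights[c])[order]
        else:
            graph = {"targets": np.empty(0, dtype=np.int64),
                     "latency": np.empty(0),
                     "indptr": np.zeros(n + 1, dtype=np.int64)}
            for c in classes:
                graph[f"w_{c.lower()}"] = np.empty(0)
        out[src_kind] = graph
    return out
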