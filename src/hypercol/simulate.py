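"""Network integration: fixed-step RK4 with latency-queued spike delivery.

The full state of the hypercolumn (membrane potentials, post-spike parameter
offsets, five double-exponential conductance channels per neuron: recurrent
AMPA/NMDA/GABA plus the LGN and background AMPA-type drives) advances on a
fixed grid of ``integration_step`` (0.2 ms).  Within a step conductances are
known in closed form, so the four RK stages evaluate them at the stage
times; spike deliveries and external Poisson events are applied at step
boundaries.  When a membrane crosses its cutoff voltage the step is redone
at finer resolution for that neuron and the residual divergence time is
added analytically, giving spike times far more accurate than the grid.

Stochastic inputs come from dedicated counter-aligned streams (wiring,
initial conditions, LGN, background) whose per-step draw counts do not
depend on the network state, so a paired run that merely omits one spike
delivery sees bit-identical noise realizations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import connectivity as conn
from .config import ConfigError, NetworkSpec, spec_hash
from .inputs import Stimulus, normalized_contrast_response, ou_stationary_sd
from .series import SignalSeries
from .synapses import kernel_normalization

__all__ = ["Recorders", "SimulationResult", "run", "run_trials",
           "perturb_single_spike", "population_indices"]

_EXP_CAP = 30.0
_POP_NAMES = {"upper_E": ("upper", "E"), "upper_I": ("upper", "I"),
              "lower_E": ("lower", "E"), "lower_I": ("lower", "I")}


@dataclass(frozen=True)
class Recorders:
    """What to record during a run (all traces sampled every step).

    ``chi_populations`` enables streaming accumulation of the voltage
    synchrony measure over whole populations (membrane potentials clipped at
    the spike threshold unless ``clip_voltage`` is off).  ``warmup_ms`` of
    initial transient is excluded from every recording and statistic.
    """

    voltage_ids: tuple = ()
    current_ids: tuple = ()
    lfp_sectors: tuple = ()  # (center_deg, width_deg) pairs
    chi_populations: tuple = ()
    input_share: bool = False
    background_rate: bool = False
    tonic_drive_probe: bool = False  # accumulate mean exc conductance per neuron
    warmup_ms: float = 500.0
    clip_voltage: bool = True


@dataclass
class SimulationResult:
    """Spike raster plus requested traces and streaming statistics."""

    spike_ids: np.ndarray
    spike_times: np.ndarray
    traces: dict
    chi: dict
    chi_components: dict
    input_share: dict | None
    mean_exc_conductance: np.ndarray | None
    angles: np.ndarray
    offsets: dict
    sizes: dict
    dt: float
    duration_ms: float
    warmup_ms: float
    seed: int
    spec_hash: str
    wiring_hash: str
    gamma: float
    stimulus: Stimulus
    spec: NetworkSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return int(sum(self.sizes.values()))

    def population_indices(self, pop: str) -> np.ndarray:
        layer, kind = _POP_NAMES[pop]
        off = self.offsets[(layer, kind)]
        return np.arange(off, off + self.sizes[(layer, kind)])

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        return self.spike_times[self.spike_ids == neuron_id]

    def firing_rates(self, window_ms: tuple | None = None) -> np.ndarray:
        """Mean rate [Hz] per neuron over the analysis window (post-warmup
        by default)."""
        lo, hi = window_ms if window_ms else (self.warmup_ms, self.duration_ms)
        sel = (self.spike_times >= lo) & (self.spike_times < hi)
        counts = np.bincount(self.spike_ids[sel], minlength=self.n_total)
        return counts * 1000.0 / (hi - lo)

    def population_rate_histogram(self, pop: str, bin_ms: float = 2.0):
        """Fraction of the population firing per bin (post-warmup)."""
        idx = self.population_indices(pop)
        sel = np.isin(self.spike_ids, idx) & (self.spike_times >= self.warmup_ms)
        edges = np.arange(self.warmup_ms, self.duration_ms + bin_ms, bin_ms)
        hist, _ = np.histogram(self.spike_times[sel], bins=edges)
        return edges[:-1], hist / idx.size


def population_indices(spec_or_result, pop: str) -> np.ndarray:
    if isinstance(spec_or_result, SimulationResult):
        return spec_or_result.population_indices(pop)
    spec = spec_or_result
    layer, kind = _POP_NAMES[pop]
    off = 0
    for l, k in conn.POPULATIONS:
        if (l, k) == (layer, kind):
            return np.arange(off, off + spec.population_size(kind))
        off += spec.population_size(k)
    raise KeyError(pop)


# --------------------------------------------------------------------------

class _Engine:
    """One network realization ready to integrate."""

    def __init__(self, spec: NetworkSpec, stimulus: Stimulus, seed: int,
                 recorders: Recorders,
                 omit_spike: tuple | None = None,
                 tonic_exc_conductance: np.ndarray | None = None,
                 matrix: conn.ConnectivityMatrix | None = None):
        spec.validate()
        self.spec, self.stim, self.seed, self.rec = spec, stimulus, int(seed), recorders
        self.dt = spec.integration_step
        self.omit = omit_spike  # (neuron_id, spike_index)
        # --- streams: wiring is quenched on the spec's master seed ---------
        wiring_rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 11]))
        self.matrix = matrix if matrix is not None else conn.build_network(spec, wiring_rng)
        self.graphs = conn.compile_graphs(self.matrix)
        self.rng_init = np.random.default_rng(np.random.SeedSequence([self.seed, 21]))
        self.rng_lgn = np.random.default_rng(np.random.SeedSequence([self.seed, 22]))
        self.rng_bg = np.random.default_rng(np.random.SeedSequence([self.seed, 23]))
        # --- per-neuron constants -----------------------------------------
        m = self.matrix
        n = m.n_total
        self.n = n
        kind = np.empty(n, dtype="U1")
        for (layer, k), off in m.offsets.items():
            kind[off:off + m.sizes[(layer, k)]] = k
        self.is_exc = kind == "E"
        pk = {k: spec.neurons[k] for k in ("E", "I")}
        self.cap = np.where(self.is_exc, pk["E"].capacitance, pk["I"].capacitance)
        self.itau0 = np.where(self.is_exc, 1.0 / pk["E"].tau_m, 1.0 / pk["I"].tau_m)
        self.el = np.where(self.is_exc, pk["E"].e_leak, pk["I"].e_leak)
        self.vt0 = np.where(self.is_exc, pk["E"].v_threshold, pk["I"].v_threshold)
        self.dt0 = np.where(self.is_exc, pk["E"].delta_t, pk["I"].delta_t)
        self.vr = np.where(self.is_exc, pk["E"].reset, pk["I"].reset)
        self.margin = np.where(self.is_exc, pk["E"].cutoff_margin, pk["I"].cutoff_margin)
        # soft refractory components (offsets live on all neurons, zero for I)
        comps = spec.refractory["E"].components if spec.refractory["E"].mode == "soft" else ()
        self.soft = [(c.target, c.amplitude, math.exp(-self.dt / c.tau)) for c in comps]
        self.offsets_state = [np.zeros(n) for _ in self.soft]
        self.tau_rp = spec.refractory["I"].refractory_period
        # --- synaptic channels --------------------------------------------
        def per_target(cls):
            e = spec.synapse_classes[f"{cls}:E"]
            i = spec.synapse_classes[f"{cls}:I"]
            tr = np.where(self.is_exc, e.tau_rise, i.tau_rise)
            td = np.where(self.is_exc, e.tau_decay, i.tau_decay)
            nrm = np.where(self.is_exc,
                           kernel_normalization(e.tau_rise, e.tau_decay),
                           kernel_normalization(i.tau_rise, i.tau_decay))
            return tr, td, nrm
        self.ch = {}
        for name, cls in (("ampa", "AMPA"), ("nmda", "NMDA"), ("gaba", "GABA"),
                          ("lgn", "AMPA"), ("bg", "AMPA")):
            tr, td, nrm = per_target(cls)
            self.ch[name] = {
                "A": np.zeros(n), "B": np.zeros(n), "norm": nrm,
                "fd": np.exp(-self.dt / td), "fr": np.exp(-self.dt / tr),
                "fd_h": np.exp(-0.5 * self.dt / td), "fr_h": np.exp(-0.5 * self.dt / tr),
                "tau_d": td, "tau_r": tr,
            }
        self.e_gaba = np.where(self.is_exc,
                               spec.synapse_classes["GABA:E"].reversal,
                               spec.synapse_classes["GABA:I"].reversal)
        self.tonic = tonic_exc_conductance  # nS at excitatory reversal, or None
        # --- delivery buffer ----------------------------------------------
        max_lat = max((w.latency for w in m.wirings), default=1.0)
        self.buf_len = int(math.ceil(max_lat / self.dt)) + 4
        self.buf = np.zeros((self.buf_len, n, 3))  # classes ampa, nmda, gaba
        for g in self.graphs.values():
            steps = g["latency"] / self.dt
            if np.any(np.abs(steps - np.rint(steps)) > 1e-9):
                import warnings
                warnings.warn("synaptic latency not a multiple of dt; "
                              "deliveries rounded to the step grid")
            g["lat_steps"] = np.rint(steps).astype(np.int64)
        # --- LGN rate decomposition: rate = base0 + base1 * n(C(t)) --------
        lgn = spec.lgn
        eps = lgn.tuning_broadness
        tuning = np.maximum((1.0 - eps) + eps * np.cos(
            np.deg2rad(2.0 * (m.angles - stimulus.orientation))), 0.0)
        lower = np.zeros(n, dtype=bool)
        for (layer, k), off in m.offsets.items():
            if layer == "lower":
                lower[off:off + m.sizes[(layer, k)]] = True
        attn = np.where(lower, lgn.lower_layer_attenuation, 1.0)
        attn = attn * np.where(self.is_exc, 1.0, lgn.inhibitory_attenuation)
        self.lgn_base0 = attn * lgn.rate_offset
        self.lgn_base1 = attn * lgn.rate_gain * tuning
        self.const_nc = (None if stimulus.flashed
                         else float(normalized_contrast_response(stimulus.contrast, lgn)))
        self.g_lgn = lgn.g_lgn
        self.bgp = spec.background

    # ------------------------------------------------------------------
    def run(self, duration_ms: float) -> SimulationResult:
        spec, rec, dt, n = self.spec, self.rec, self.dt, self.n
        if duration_ms < dt:
            raise ConfigError("duration must be at least one step")
        n_steps = int(round(duration_ms / dt))
        warm_steps = min(int(round(rec.warmup_ms / dt)), n_steps)
        n_rec = n_steps - warm_steps
        fs = 1000.0 / dt
        # state ------------------------------------------------------------
        v = self.el + self.rng_init.uniform(-5.0, 5.0, n)
        refr_until = np.full(n, -np.inf)
        bg_rate = float(self.bgp.mean_rate
                        + ou_stationary_sd(self.bgp) * self.rng_init.standard_normal())
        ch = self.ch
        fast = ("ampa", "lgn", "bg")
        # recorders ----------------------------------------------------------
        v_ids = np.asarray(rec.voltage_ids, dtype=np.int64)
        c_ids = np.asarray(rec.current_ids, dtype=np.int64)
        v_tr = np.empty((v_ids.size, n_rec)) if v_ids.size else None
        c_tr = np.empty((c_ids.size, n_rec)) if c_ids.size else None
        sectors = []
        for center, width in rec.lfp_sectors:
            idx = self._sector_indices(center, width)
            if idx.size == 0:
                raise ConfigError(f"empty LFP sector at {center} deg")
            sectors.append((center, width, idx, np.empty(n_rec)))
        chi_pops = []
        for pop in rec.chi_populations:
            idx = population_indices(self, pop) if False else self._pop_idx(pop)
            chi_pops.append((pop, idx, np.empty(n_rec), np.zeros(idx.size),
                             np.zeros(idx.size)))
        bg_tr = np.empty(n_rec) if rec.background_rate else None
        share = ({"lgn": np.zeros(n), "recurrent": np.zeros(n),
                  "background": np.zeros(n), "g_lgn": np.zeros(n),
                  "g_recurrent": np.zeros(n), "g_background": np.zeros(n)}
                 if rec.input_share else None)
        gexc_accum = np.zeros(n) if rec.tonic_drive_probe else None
        spike_ids: list[np.ndarray] = []
        spike_times: list[np.ndarray] = []
        spike_counts = np.zeros(n, dtype=np.int64)
        omit_id, omit_idx = self.omit if self.omit is not None else (-1, -1)
        graphs = self.graphs
        buf, buf_len = self.buf, self.buf_len
        coef = 1e-3 / self.cap  # nS*mV -> nA, then /C
        exp_cap = _EXP_CAP
        # ------------------------------------------------------------------
        for k in range(n_steps):
            t = k * dt
            # 1) deliveries scheduled for this step
            slot = buf[k % buf_len]
            for ci, name in enumerate(("ampa", "nmda", "gaba")):
                col = slot[:, ci]
                if col.any():
                    c = ch[name]
                    inc = c["norm"] * col
                    c["A"] += inc
                    c["B"] += inc
            slot[:] = 0.0
            # 2) external events (fixed draw counts per step)
            nc = (self.const_nc if self.const_nc is not None
                  else float(normalized_contrast_response(
                      self.stim.contrast_at(t), self.spec.lgn)))
            lgn_mean = (self.lgn_base0 + self.lgn_base1 * nc) * (dt * 1e-3)
            lgn_counts = self.rng_lgn.poisson(lgn_mean)
            z = self.rng_bg.standard_normal()
            decay = math.exp(-dt / self.bgp.filter_time)
            bg_rate = (self.bgp.mean_rate + (bg_rate - self.bgp.mean_rate) * decay
                       + ou_stationary_sd(self.bgp) * math.sqrt(1.0 - decay * decay) * z)
            bg_counts = self.rng_bg.poisson(max(bg_rate, 0.0) * dt * 1e-3, n)
            c = ch["lgn"]
            inc = c["norm"] * (self.g_lgn * lgn_counts)
            c["A"] += inc
            c["B"] += inc
            c = ch["bg"]
            inc = c["norm"] * (self.bgp.g_bg * bg_counts)
            c["A"] += inc
            c["B"] += inc
            # 3) conductances at the three stage times
            a_f = ch["ampa"]["A"] + ch["lgn"]["A"] + ch["bg"]["A"]
            b_f = ch["ampa"]["B"] + ch["lgn"]["B"] + ch["bg"]["B"]
            cf, cn, cg = ch["ampa"], ch["nmda"], ch["gaba"]
            ge0 = (a_f - b_f) + (cn["A"] - cn["B"])
            geh = (a_f * cf["fd_h"] - b_f * cf["fr_h"]
                   + cn["A"] * cn["fd_h"] - cn["B"] * cn["fr_h"])
            ge1 = (a_f * cf["fd"] - b_f * cf["fr"]
                   + cn["A"] * cn["fd"] - cn["B"] * cn["fr"])
            gg0 = cg["A"] - cg["B"]
            ggh = cg["A"] * cg["fd_h"] - cg["B"] * cg["fr_h"]
            gg1 = cg["A"] * cg["fd"] - cg["B"] * cg["fr"]
            if self.tonic is not None:
                ge0 = ge0 + self.tonic
                geh = geh + self.tonic
                ge1 = ge1 + self.tonic
            # 4) recording at step start
            if k >= warm_steps:
                j = k - warm_steps
                if v_tr is not None:
                    v_tr[:, j] = v[v_ids]
                if c_tr is not None or sectors or share is not None or gexc_accum is not None:
                    i_exc = ge0 * (0.0 - v) * 1e-3
                    i_gab = gg0 * (self.e_gaba - v) * 1e-3
                    i_tot = i_exc + i_gab
                    if c_tr is not None:
                        c_tr[:, j] = i_tot[c_ids]
                    for _, _, idx, tr in sectors:
                        tr[j] = i_tot[idx].mean()
                    if share is not None:
                        g_lgn = ch["lgn"]["A"] - ch["lgn"]["B"]
                        g_bg = ch["bg"]["A"] - ch["bg"]["B"]
                        g_exc_rec = (ch["ampa"]["A"] - ch["ampa"]["B"]
                                     + cn["A"] - cn["B"])
                        share["lgn"] += np.abs(g_lgn * v) * 1e-3
                        share["recurrent"] += (np.abs(g_exc_rec * v) * 1e-3
                                               + np.abs(i_gab))
                        share["background"] += np.abs(g_bg * v) * 1e-3
                        share["g_lgn"] += g_lgn
                        share["g_recurrent"] += g_exc_rec + gg0
                        share["g_background"] += g_bg
                    if gexc_accum is not None:
                        gexc_accum += ch["ampa"]["A"] - ch["ampa"]["B"] + cn["A"] - cn["B"]
                for pop, idx, mtr, s1, s2 in chi_pops:
                    vv = v[idx]
                    if rec.clip_voltage:
                        vv = np.minimum(vv, self.vt0[idx])
                    mtr[j] = vv.mean()
                    s1 += vv
                    s2 += vv * vv
                if bg_tr is not None:
                    bg_tr[j] = bg_rate
            # 5) effective parameters and RK4
            vt_eff = self.vt0.copy()
            dl_eff = self.dt0.copy()
            it_eff = self.itau0.copy()
            for (target, _, _), off in zip(self.soft, self.offsets_state):
                if target == "v_threshold":
                    vt_eff += off
                elif target == "delta_t":
                    dl_eff += off
                else:
                    it_eff += off
            active = t >= refr_until
            k1 = self._rhs(v, ge0, gg0, vt_eff, dl_eff, it_eff, coef)
            v2 = v + (0.5 * dt) * k1
            k2 = self._rhs(v2, geh, ggh, vt_eff, dl_eff, it_eff, coef)
            v3 = v + (0.5 * dt) * k2
            k3 = self._rhs(v3, geh, ggh, vt_eff, dl_eff, it_eff, coef)
            v4 = v + dt * k3
            k4 = self._rhs(v4, ge1, gg1, vt_eff, dl_eff, it_eff, coef)
            v_new = v + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            # numerical guard: extreme total conductance makes the membrane
            # equation stiff for the explicit scheme; clamp the excursion so
            # a pathological (e.g. runaway) state saturates instead of
            # overflowing
            v_new = np.maximum(v_new, -150.0)
            v_cut = vt_eff + self.margin * dl_eff
            crossed = active & (~np.isfinite(v_new) | (v_new >= v_cut))
            v_new = np.where(active, v_new, self.vr)
            if np.any(crossed):
                ids = np.nonzero(crossed)[0]
                t_sp = self._refine_spikes(ids, v[ids], t, vt_eff[ids], dl_eff[ids],
                                           it_eff[ids], v_cut[ids],
                                           (ge0, geh, ge1), (gg0, ggh, gg1), coef)
                spike_ids.append(ids)
                spike_times.append(t_sp)
                v_new[ids] = self.vr[ids]
                # post-spike updates
                exc_sp = ids[self.is_exc[ids]]
                if exc_sp.size:
                    for (tgt, amp, _), off in zip(self.soft, self.offsets_state):
                        off[exc_sp] = amp  # reset, not summed
                inh_sp = ids[~self.is_exc[ids]]
                if inh_sp.size:
                    refr_until[inh_sp] = t_sp[~self.is_exc[ids]] + self.tau_rp
                # deliveries
                for i, tsp in zip(ids, t_sp):
                    cnt = spike_counts[i]
                    spike_counts[i] += 1
                    if i == omit_id and cnt == omit_idx:
                        continue  # omitted spike: reset happened, no delivery
                    g = graphs["E"] if self.is_exc[i] else graphs["I"]
                    lo, hi = g["indptr"][i], g["indptr"][i + 1]
                    if hi == lo:
                        continue
                    tg = g["targets"][lo:hi]
                    arr_step = np.maximum(
                        np.rint(tsp / dt).astype(np.int64) + g["lat_steps"][lo:hi],
                        k + 1)
                    sl = arr_step % buf_len
                    if self.is_exc[i]:
                        np.add.at(buf, (sl, tg, 0), g["w_ampa"][lo:hi])
                        np.add.at(buf, (sl, tg, 1), g["w_nmda"][lo:hi])
                    else:
                        np.add.at(buf, (sl, tg, 2), g["w_gaba"][lo:hi])
            v = v_new
            # 6) decay of channels and post-spike offsets
            for name in ("ampa", "nmda", "gaba", "lgn", "bg"):
                c = ch[name]
                c["A"] *= c["fd"]
                c["B"] *= c["fr"]
            for (tgt, _, dec), off in zip(self.soft, self.offsets_state):
                off *= dec
        # ------------------------------------------------------------------
        ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int64)
        times = np.concatenate(spike_times) if spike_times else np.empty(0)
        order = np.argsort(times, kind="stable")
        traces: dict[str, SignalSeries] = {}
        if v_tr is not None:
            for row, nid in enumerate(v_ids):
                traces[f"v:{nid}"] = SignalSeries(v_tr[row], fs, "mV", {"neuron": int(nid)})
        if c_tr is not None:
            for row, nid in enumerate(c_ids):
                traces[f"i:{nid}"] = SignalSeries(c_tr[row], fs, "nA", {"neuron": int(nid)})
        for center, width, idx, tr in sectors:
            traces[f"lfp:{center:g}:{width:g}"] = SignalSeries(
                tr, fs, "nA", {"sector_center": center, "sector_width": width,
                               "n_neurons": int(idx.size)})
        if bg_tr is not None:
            traces["bg_rate"] = SignalSeries(bg_tr, fs, "Hz")
        chi, chi_comp = {}, {}
        for pop, idx, mtr, s1, s2 in chi_pops:
            var_mean = float(np.var(mtr))
            var_i = s2 / n_rec - (s1 / n_rec) ** 2
            mean_var = float(np.mean(var_i))
            if mean_var <= 0:
                raise ConfigError(f"zero-variance voltages in population {pop}")
            chi[pop] = math.sqrt(var_mean / mean_var)
            chi_comp[pop] = {"var_of_mean": var_mean, "mean_of_var": mean_var,
                             "n": int(idx.size)}
            traces[f"vmean:{pop}"] = SignalSeries(mtr, fs, "mV", {"population": pop})
        share_out = None
        if share is not None:
            share_out = {kk: vv / n_rec for kk, vv in share.items()}
        return SimulationResult(
            spike_ids=ids[order], spike_times=times[order], traces=traces,
            chi=chi, chi_components=chi_comp, input_share=share_out,
            mean_exc_conductance=(gexc_accum / n_rec if gexc_accum is not None else None),
            angles=self.matrix.angles, offsets=dict(self.matrix.offsets),
            sizes=dict(self.matrix.sizes), dt=dt, duration_ms=n_steps * dt,
            warmup_ms=warm_steps * dt, seed=self.seed,
            spec_hash=spec_hash(spec), wiring_hash=self.matrix.content_hash(),
            gamma=spec.interlayer_scale, stimulus=self.stim, spec=spec)

    # ------------------------------------------------------------------
    def _rhs(self, v, ge, gg, vt, dl, it, coef):
        arg = np.minimum((v - vt) / dl, _EXP_CAP)
        psi = dl * np.exp(arg)
        return it * (self.el - v + psi) + (gg * (self.e_gaba - v) - ge * v) * coef

    def _refine_spikes(self, ids, v0, t0, vt, dl, it, v_cut,
                       ge_stages, gg_stages, coef, n_sub: int = 16):
        """Re-integrate the crossing step at finer resolution for the
        handful of neurons that reached cutoff, then extrapolate the
        residual divergence time analytically."""
        dt = self.dt
        h = dt / n_sub
        # closed-form conductance interpolation: per-channel decay over h
        cf, cn, cg = self.ch["ampa"], self.ch["nmda"], self.ch["gaba"]
        a_f = (cf["A"] + self.ch["lgn"]["A"] + self.ch["bg"]["A"])[ids]
        b_f = (cf["B"] + self.ch["lgn"]["B"] + self.ch["bg"]["B"])[ids]
        a_n, b_n = cn["A"][ids], cn["B"][ids]
        a_g, b_g = cg["A"][ids], cg["B"][ids]
        tonic = self.tonic[ids] if self.tonic is not None else 0.0
        fd_f = np.exp(-h / cf["tau_d"][ids]); fr_f = np.exp(-h / cf["tau_r"][ids])
        fd_n = np.exp(-h / cn["tau_d"][ids]); fr_n = np.exp(-h / cn["tau_r"][ids])
        fd_g = np.exp(-h / cg["tau_d"][ids]); fr_g = np.exp(-h / cg["tau_r"][ids])
        fd_fh = np.sqrt(fd_f); fr_fh = np.sqrt(fr_f)
        fd_nh = np.sqrt(fd_n); fr_nh = np.sqrt(fr_n)
        fd_gh = np.sqrt(fd_g); fr_gh = np.sqrt(fr_g)
        el, e_g, cc = self.el[ids], self.e_gaba[ids], coef[ids]

        def rhs(vv, ge, gg):
            arg = np.minimum((vv - vt) / dl, _EXP_CAP)
            return it * (el - vv + dl * np.exp(arg)) + (gg * (e_g - vv) - ge * vv) * cc

        v = v0.copy()
        t_sp = np.full(ids.size, np.nan)
        done = np.zeros(ids.size, dtype=bool)
        for j in range(n_sub):
            ge0 = a_f - b_f + a_n - b_n + tonic
            geh = a_f * fd_fh - b_f * fr_fh + a_n * fd_nh - b_n * fr_nh + tonic
            ge1 = a_f * fd_f - b_f * fr_f + a_n * fd_n - b_n * fr_n + tonic
            gg0 = a_g - b_g
            ggh = a_g * fd_gh - b_g * fr_gh
            gg1 = a_g * fd_g - b_g * fr_g
            k1 = rhs(v, ge0, gg0)
            k2 = rhs(v + 0.5 * h * k1, geh, ggh)
            k3 = rhs(v + 0.5 * h * k2, geh, ggh)
            k4 = rhs(v + h * k3, ge1, gg1)
            v_new = v + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            cross = ~done & (~np.isfinite(v_new) | (v_new >= v_cut))
            if np.any(cross):
                # extrapolate from the crossing voltage where RK is still
                # accurate; residual time under pure exponential growth
                v_ref = np.where(np.isfinite(v_new) & (v_new < 2 * np.abs(v_cut) + 1e3),
                                 np.maximum(v_new, v_cut), v_cut)
                rem = (1.0 / it) * np.exp(
                    -np.clip((v_ref - vt) / dl, 0.0, _EXP_CAP))
                t_sp = np.where(cross, t0 + (j + 1) * h + rem, t_sp)
                done |= cross
            v = np.where(done, v, v_new)
            if done.all():
                break
            a_f *= fd_f; b_f *= fr_f
            a_n *= fd_n; b_n *= fr_n
            a_g *= fd_g; b_g *= fr_g
        # neurons flagged by the coarse step but not re-crossing at fine
        # resolution (borderline trajectories): book the spike at step end
        miss = ~done
        if np.any(miss):
            t_sp = np.where(miss, t0 + dt, t_sp)
        return t_sp

    # ------------------------------------------------------------------
    def _pop_idx(self, pop: str) -> np.ndarray:
        layer, kind = _POP_NAMES[pop]
        off = self.matrix.offsets[(layer, kind)]
        return np.arange(off, off + self.matrix.sizes[(layer, kind)])

    def _sector_indices(self, center: float, width: float) -> np.ndarray:
        """Upper-layer neurons (both kinds) within the angular sector."""
        parts = []
        for pop in ("upper_E", "upper_I"):
            idx = self._pop_idx(pop)
            d = conn.wrap_angle(self.matrix.angles[idx] - center)
            parts.append(idx[(d >= -width / 2.0) & (d < width / 2.0)])
        return np.concatenate(parts)


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------

def run(spec: NetworkSpec, stimulus: Stimulus, duration_ms: float,
        recorders: Recorders = Recorders(), seed: int = 0, *,
        tonic_exc_conductance: np.ndarray | None = None,
        _omit_spike: tuple | None = None,
        _matrix: conn.ConnectivityMatrix | None = None) -> SimulationResult:
    """Integrate the network for ``duration_ms``.

    Deterministic given (spec, stimulus, seed): the wiring is drawn from the
    spec's master seed, noise streams from ``seed``.
    ``tonic_exc_conductance`` adds a constant per-neuron conductance [nS] at
    the excitatory reversal (used by drive-compensation experiments).
    """
    eng = _Engine(spec, stimulus, seed, recorders, omit_spike=_omit_spike,
                  tonic_exc_conductance=tonic_exc_conductance, matrix=_matrix)
    return eng.run(duration_ms)


def run_trials(spec: NetworkSpec, stimulus: Stimulus, n_trials: int,
               seed_schedule=None, duration_ms: float = 1500.0,
               recorders: Recorders = Recorders(warmup_ms=0.0)) -> list:
    """Repeat the stimulus over independent noise realizations on one fixed
    wiring realization (quenched disorder)."""
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if seed_schedule is None:
        seed_schedule = [1000 + 7 * i for i in range(n_trials)]
    seeds = list(seed_schedule)
    if len(seeds) != n_trials:
        raise ConfigError("seed_schedule length must equal n_trials")
    wiring_rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 11]))
    matrix = conn.build_network(spec.validate(), wiring_rng)
    return [run(spec, stimulus, duration_ms, recorders, seed=s, _matrix=matrix)
            for s in seeds]


def perturb_single_spike(spec: NetworkSpec, stimulus: Stimulus, duration_ms: float,
                         seed: int, target_neuron: int, target_spike_index: int,
                         recorders: Recorders = Recorders()):
    """Paired runs differing only in the delivery of one spike.

    The perturbed run shares the wiring and every stochastic input draw with
    the unperturbed one; the indexed spike of ``target_neuron`` is not
    delivered to any target, while the emitting neuron's own reset (and
    post-spike parameter offsets) still happen.
    """
    base = run(spec, stimulus, duration_ms, recorders, seed)
    n_spikes = int(np.sum(base.spike_ids == target_neuron))
    if target_spike_index >= n_spikes:
        raise ConfigError(
            f"neuron {target_neuron} fired only {n_spikes} spikes; "
            f"index {target_spike_index} absent")
    pert = run(spec, stimulus, duration_ms, recorders, seed,
               _omit_spike=(int(target_neuron), int(target_spike_index)))
    return base, pert
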