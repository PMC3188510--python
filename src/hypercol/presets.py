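"""Experiment presets: canned simulate->analyze protocols.

Each preset runs a complete protocol (possibly at a reduced network scale)
and writes its artifacts plus a JSON manifest recording the resolved
configuration, seeds and content hashes, so a run is reproducible from the
manifest alone.
"""
from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from . import analysis, io
from .chaos import (auto_epsilon, autocorrelation_delay, delay_embed,
                    divergence_curve, estimate_lambda_max)
from .config import ConfigError, NetworkSpec, load_preset, spec_hash, default_spec
from .inputs import Stimulus
from .simulate import Recorders, run, perturb_single_spike

__all__ = ["EXPERIMENT_PRESETS", "run_preset"]


def _scaled(spec: NetworkSpec, scale: float) -> NetworkSpec:
    from .config import scale_network
    n_exc = max(8, int(round(spec.ref_n_exc * scale)))
    return scale_network(spec, n_exc, on_overflow="clip")


def _chi_vs_contrast(spec, scale, seed, outdir, duration_ms=6000.0):
    spec = _scaled(spec, scale)
    rows = []
    for c in (0.0, 0.02, 0.1, 0.3, 0.6, 0.95):
        res = run(spec, Stimulus(contrast=c), duration_ms,
                  Recorders(chi_populations=("upper_E",), warmup_ms=1000.0),
                  seed=seed)
        rows.append({"contrast": c, "chi": res.chi["upper_E"]})
    path = outdir / "chi_vs_contrast.json"
    io.write_json(rows, path)
    return [path]


def _chi_vs_size(spec, scale, seed, outdir, duration_ms=6000.0):
    rows = []
    for frac, nseeds in ((scale / 4, 3), (scale / 2, 3), (scale, 3)):
        sub = _scaled(spec, frac)
        chis = [run(sub, Stimulus(contrast=0.02), duration_ms,
                    Recorders(chi_populations=("upper_E",), warmup_ms=1000.0),
                    seed=seed + i).chi["upper_E"] for i in range(nseeds)]
        rows.append({"n_total": sub.n_total, "chi": chis})
    fit = analysis.chi_scaling([r["n_total"] for r in rows],
                               [r["chi"] for r in rows], rng=seed)
    path = outdir / "chi_vs_size.json"
    io.write_json({"rows": rows, "fit": fit}, path)
    return [path]


def _regime_overview(spec, scale, seed, outdir, duration_ms=8000.0):
    spec = _scaled(spec, scale)
    arts = []
    ref = None
    for c in (0.0, 0.02, 0.95):
        res = run(spec, Stimulus(contrast=c), duration_ms,
                  Recorders(chi_populations=("upper_E",),
                            lfp_sectors=((0.0, 18.0),), warmup_ms=1000.0),
                  seed=seed)
        h5 = outdir / f"run_C{int(100 * c)}.h5"
        io.write_result(res, h5)
        arts.append(h5)
        lfp = analysis.lfp_signal(res, 0.0, 18.0)
        if c == 0.0:
            ref = lfp
        spec_est = analysis.power_spectrum(lfp, reference=ref)
        path = outdir / f"spectrum_C{int(100 * c)}.json"
        io.write_json({"f": spec_est.frequencies, "power": spec_est.values,
                       "chi": res.chi["upper_E"]}, path)
        arts.append(path)
    return arts


def _psp_calibration(spec, scale, seed, outdir):
    from .synapses import psp_peak, calibrate_gaba_reversal
    rows = []
    for key, sc in spec.synapse_classes.items():
        if sc.reference_psp is None:
            continue
        rows.append({"class": key,
                     "psp_mV": psp_peak(spec.neurons[sc.target_kind], sc),
                     "reference_mV": sc.reference_psp})
    fitted = calibrate_gaba_reversal(spec.neurons, spec.synapse_classes)
    path = outdir / "psp_calibration.json"
    io.write_json({"rows": rows, "fitted_gaba_reversal_mV": fitted}, path)
    return [path]


def _perturbation(spec, scale, seed, outdir):
    spec = _scaled(spec, scale)
    stim = Stimulus(contrast=0.95)
    probe = run(spec, stim, 2000, Recorders(warmup_ms=500.0), seed=seed)
    ui = probe.population_indices("upper_I")
    rates = probe.firing_rates()
    cand = ui[np.abs(probe.angles[ui]) < 5.0]
    target = int(cand[np.argmax(rates[cand])])
    base, pert = perturb_single_spike(
        spec, stim, 3000, seed, target, 3,
        Recorders(warmup_ms=500.0, lfp_sectors=((0.0, 18.0),)))
    arts = []
    for tag, res in (("base", base), ("pert", pert)):
        p = outdir / f"perturb_{tag}.h5"
        io.write_result(res, p)
        arts.append(p)
    return arts


def _chaos_lfp(spec, scale, seed, outdir, duration_ms=30000.0):
    spec = _scaled(spec, scale)
    res = run(spec, Stimulus(contrast=0.95), duration_ms,
              Recorders(lfp_sectors=((0.0, 18.0),), warmup_ms=1000.0), seed=seed)
    lfp = analysis.lfp_signal(res, 0.0, 18.0)
    tau = max(1, autocorrelation_delay(lfp))
    curves = []
    for m in (3, 4, 5):
        emb = delay_embed(lfp, m, tau)
        eps = auto_epsilon(emb, rng=seed)
        try:
            curves.append(divergence_curve(emb, eps, horizon=10 * tau,
                                           min_pairs=200, theiler=2 * tau,
                                           rng=seed))
        except Exception:
            pass
    report = {"delay_samples": tau, "gamma": spec.interlayer_scale}
    if len(curves) >= 2:
        est = estimate_lambda_max(curves)
        report.update({"verdict": est.verdict, "lambda_max_per_ms": est.lambda_max,
                       "slopes": {str(k): v for k, v in est.per_dimension_slopes.items()}})
    else:
        report["verdict"] = "no linear scaling region"
    path = outdir / "chaos_report.json"
    io.write_json(report, path)
    return [path]


def _full_scale_coherence(spec, scale, seed, outdir):
    """Reference-size MUA-LFP coherence protocol (long; hours at scale 1)."""
    spec = _scaled(spec, scale)
    res = run(spec, Stimulus(contrast=0.95), 100_500.0,
              Recorders(lfp_sectors=((0.0, 18.0),), warmup_ms=500.0), seed=seed)
    est = analysis.mua_lfp_coherence(res, 0.0, rng=seed)
    path = outdir / "mua_lfp_coherence.json"
    io.write_json({"f": est.frequencies, "coherence": est.values}, path)
    return [path]


EXPERIMENT_PRESETS = {
    "psp-calibration": _psp_calibration,
    "fig6-chi-vs-contrast": _chi_vs_contrast,
    "fig6-chi-vs-size": _chi_vs_size,
    "regime-overview": _regime_overview,
    "single-spike-perturbation": _perturbation,
    "chaos-lfp": _chaos_lfp,
    "fig8-mua-lfp-coherence": _full_scale_coherence,
}


def run_preset(name: str, scale_factor: float = 0.125, seed: int = 0,
               outdir: str | Path = "preset_out",
               config: NetworkSpec | str | None = None,
               duration_ms: float | None = None) -> dict:
    """Execute a named protocol and return its manifest (also written to
    ``outdir/manifest.json``)."""
    if name not in EXPERIMENT_PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: "
                          f"{sorted(EXPERIMENT_PRESETS)}")
    if config is None:
        spec = default_spec()
    elif isinstance(config, NetworkSpec):
        spec = config
    else:
        spec = load_preset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    import inspect
    fn = EXPERIMENT_PRESETS[name]
    kwargs = {}
    if duration_ms is not None and "duration_ms" in inspect.signature(fn).parameters:
        kwargs["duration_ms"] = duration_ms
    artifacts = fn(spec, scale_factor, seed, outdir, **kwargs)
    manifest = {
        "preset": name, "scale_factor": scale_factor, "seed": seed,
        "spec_hash": spec_hash(spec),
        "artifacts": [str(p) for p in artifacts],
        "elapsed_s": round(time.time() - t0, 2),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
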