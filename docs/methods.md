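# Model and methods

`hypercol` implements a two-layer ring network ("hypercolumn") of primary
visual cortex: two coupled rings of exponential integrate-and-fire (EIF)
neurons, each ring holding an excitatory and an inhibitory population laid
out on a regular grid of preferred orientations θ ∈ [−90°, +90°), driven by
a contrast- and orientation-tuned thalamic (LGN) Poisson input and a shared
Ornstein–Uhlenbeck background. The analysis layer computes the statistics
used to characterize its dynamics — orientation tuning, contrast-response
fits, the voltage synchrony measure χ and its finite-size scaling,
correlograms, LFP/MUA spectra and coherence, peristimulus histograms — and a
nonlinear time-series module estimates the largest Lyapunov exponent of LFP
recordings by delay embedding.

## Single-neuron dynamics

The membrane potential obeys

    dV/dt = [E_L − V + Ψ(V)] / τ_m(t) + I_syn / C,
    Ψ(V) = Δ_T · exp((V − V_T(t)) / Δ_T(t)),

with spike emission identified with the finite-time divergence of V.
Baseline parameters: excitatory τ_m = 23.30 ms, C = 0.26 nF; inhibitory
cells use the same E_L = −57.8 mV, V_T = −45.2 mV, Δ_T = 1.2 mV with halved
capacitance and time constant.

Refractoriness differs by cell class. After an excitatory spike the
effective threshold acquires two additive offsets (22.9 mV with τ = 14.7 ms
and 13.5 mV with τ = 76.2 ms), the slope factor one offset (10.0 mV,
τ = 17.7 ms) and the inverse time constant one offset (0.14 ms⁻¹,
τ = 14.3 ms); each offset decays exponentially and is **reset, not summed**,
on the next spike — excitatory inter-spike intervals are long enough that
the distinction rarely matters, and the reset form keeps the state bounded.
Offsets are updated every integration step (cheap closed-form decay).
Inhibitory cells instead use a hard refractory period (2 ms, a conventional
fast-spiking value; the published text gives none) during which integration
is suspended with V held at the reset value.

The reset potential is E_L (not published; configurable). Numerical
integration of V stops at a cutoff V_cut = V_T + 10 Δ_T, where the
exponential term exceeds the leak more than tenfold; the remaining time to
divergence is added analytically as τ_m · exp(−(V − V_T)/Δ_T). Because the
coarse step can overshoot the cutoff, the crossing step is re-integrated at
16× finer resolution for the affected neurons before extrapolating; the
resulting per-event spike-time error is below 0.02 ms against a 1000×-finer
reference at the default step.

## Synapses

Three conductance classes (AMPA, NMDA, GABA) with unit-peak
difference-of-exponentials kernels; the current is g · s(t) · (E_syn − V).
Kinetics and peak conductances (reference network size):

| class | target | τ_rise | τ_decay | g (nS) | PSP (mV) |
|-------|--------|--------|---------|--------|----------|
| AMPA  | E      | 1 | 3  | 1.0  | 0.84 |
| AMPA  | I      | 1 | 3  | 1.5  | 2.07 |
| GABA  | E      | 1 | 4  | 4.0  | 1.13 |
| GABA  | I      | 1 | 2  | 4.0  | 1.36 |
| NMDA  | E      | 3 | 80 | 0.14 | 0.50 |

NMDA carries no voltage-dependent block (a slow AMPA-like class) and, per
the efficacy table, targets excitatory cells only. Kernels are realized as
two exponential state variables per class and neuron, incremented at each
(latency-delayed) arrival — mathematically identical to summing kernels,
O(1) per spike. Reversal potentials are not published; E_AMPA = E_NMDA =
0 mV, and E_GABA is fixed by the one-scalar calibration against the PSP
column: −75.0 mV reproduces *both* printed IPSP amplitudes to within 1%
(−70 mV misses them by ~30%), while the AMPA/NMDA rows are reproduced to
<2% with no free parameter — a strong end-to-end check of units, kernels
and membrane integration.

## Connectivity and size scaling

Connection probability between two cells depends only on their orientation
distance Δθ through a rectified cosine with 180° periodicity, normalized so
that its **ring average equals p⁽⁰⁾**:

    p(Δθ) = p⁽⁰⁾ · [1 + (p⁽¹⁾/p⁽⁰⁾) cos 2Δθ]₊ / ⟨[1 + (p⁽¹⁾/p⁽⁰⁾) cos 2·]₊⟩.

The normalization is required by the published mean-target counts: the
lower-E→upper-I row (p⁽⁰⁾ = 0.07, p⁽¹⁾ = 0.16, rectification active) is
printed as ~70 targets = 0.07 × 1000, which a plain rectified profile
(mean ≈ 0.091) cannot produce. Wiring is an independent Bernoulli draw per
ordered pair, no autapses, quenched per master seed. Latencies: 1 ms
intra-layer and lower→upper, 3 ms upper→lower. The inter-layer scale Γ
multiplies inter-layer peak conductances; by default it applies to both
directions (`gamma_scope: lower_to_upper` restricts it).

For a network of size N the probability profile is multiplied by
s = p̄ / (x(p̄ − q̄) + q̄) and the pathway's conductances by 1/(s·x), where
x = N_src/N_src_ref, p̄ = p⁽⁰⁾ and q̄ is the ring average of the squared
profile. This choice preserves **exactly** both the spatial mean and the
quenched across-neuron variance of the summed input conductance at fixed
presynaptic rates (the expected in-degree × conductance product is
invariant). Below ~1/10 of the reference size the scaled intra-layer
inhibitory profile would exceed probability one; strict mode raises, and a
documented `clip` mode saturates the profile at 1 and re-chooses the
conductance to preserve the mean drive (the quenched variance is then
slightly low at the smallest sizes).

## External drives

LGN: each cell receives an independent Poisson train through a 1 nS
AMPA-type synapse at rate

    ν(θ, C) = a · [ν⁰ + ν¹ · n(C) · ((1−ε) + ε cos 2(θ−θ₀))₊],

ν⁰ = 150 Hz, ν¹ = 2850 Hz, ε = 1, a = 1 (upper layer) or 0.5 (lower). The
normalized contrast response n(C) = ln(1 + βC)/ln(1 + β) with β = 100 is
the logarithmic mapping consistent with the 30-afferent reading of the
rate table (30 × [5 Hz + 48 Hz·log₁₀(1+100C)] ≈ 150 + 2850·n(C)); the
single-afferent helper saturates at 48 Hz. A flashed stimulus alternates
0.5 s at C with 1 s at zero contrast. `lgn.inhibitory_attenuation`
optionally scales the rate onto interneurons (default 1, see "Operating
point" below).

Background: one 10 nS AMPA-type synapse per cell, driven by independent
Poisson trains that all share one instantaneous rate R_bg(t) following an
OU process (mean 10 Hz, stationary SD 1 Hz — the table's "volatility" is
interpreted as the stationary SD — correlation time 10 ms), advanced with
the exact discretization and rectified at zero only when generating events.
Event counts per step are Poisson draws (exact for piecewise-constant
rates), so no thinning error arises even at rate·dt > 0.2.

## Integration scheme

Fixed-step classical RK4 at dt = 0.2 ms. Within a step all conductances are
known in closed form, so the stages evaluate them at the stage times;
spike deliveries and external events are applied at step boundaries
(latencies are multiples of dt at the defaults; others are rounded with a
warning). Initial potentials are uniform in [E_L − 5, E_L + 5] mV and a
500 ms warm-up (1 s for the regime analyses) is discarded. Stochastic
draws come from per-purpose streams (wiring, initial state, LGN,
background) whose per-step draw counts are independent of network
activity, which is what makes the single-spike-perturbation experiment
exact: the paired run omits one spike's delivery while every noise draw is
bit-identical. A voltage floor at −150 mV guards the explicit scheme
against the stiffness of pathological high-conductance states.

## Analysis conventions

- **Tuning**: circular variance 1 − |Σ r e^{2iθ}/Σ r|; circular skewness is
  the rate-weighted third moment of the wrapped deviation from the
  preferred orientation, normalized by the second moment^(3/2) (zero for
  symmetric curves; the published normalization is not recoverable from the
  text, so the implementation pins the symmetry-zero contract and
  quadrature oracles).
- **CRF**: hyperbolic-ratio (Naka–Rushton) least squares via trust-region
  `curve_fit`, with a degeneracy flag when C₅₀ is unidentifiable.
- **χ**: √(Var_t[mean V] / mean_i Var_t[V_i]) over a whole population,
  accumulated streaming during the run; voltages are clipped at V_T by
  default so the statistic reflects sub-threshold synchrony. χ(N) is fitted
  as √(a + b/N) plus a log–log slope with a bootstrap interval.
- **LFP**: mean total synaptic input current (nA) over the upper-layer
  cells of a 9° sector (200 E + 50 I at reference density — the published
  contributing counts fix the width), sampled at 5 kHz. The
  pairwise-correlation selection region stays 18° as printed, with a
  ≥100-spike requirement for spike-train pairs and a 10 ms square smoothing
  window (width not published; sensitivity covered in tests).
- **Spectra/coherence**: Welch (1 s Hann segments, 50% overlap), power
  normalized to unit value at the 0 Hz anchor of the zero-contrast
  reference; MUA is the sum of three random sector cells' trains smoothed
  by a unit-integral Gaussian (σ = 1 ms); coherence is the magnitude
  |S_xy|/√(S_xx S_yy), averaged over 20 triplets (silent triplets are
  redrawn).
- **PSTH**: counts / trials / cells in 2 ms bins, stimulus-aligned.
- **Feed-forward share**: reported as the share of the time-averaged
  synaptic *conductance* (G_LGN/(G_LGN + G_recurrent)); the absolute-current
  variant is recorded too. Only the conductance reading is consistent with
  the published conductance anchors and bounds simultaneously.

## Chaos module

Delay embedding s_n = (x_n, x_{n−τ}, …, x_{n−(m−1)τ}) with the delay
defaulting to the first autocorrelation zero. False nearest neighbors use
the distance-ratio criterion (default R* = 10, stable over 5–15) with a
Theiler exclusion window and a numerical floor that treats coincident
points (exactly periodic signals) as true neighbors. The divergence curve
S(Δn) is the mean log distance at horizon Δn of initially ε-close
neighborhoods; λ_max is the common slope of the linear sections, found
automatically as the longest window with all-positive local slopes varying
less than 20%, a total rise of at least 0.5 nats, and slopes agreeing
within 20% across embedding dimensions — otherwise the verdict is "no
linear scaling region". The pipeline recovers ln 2 for the fully chaotic
logistic map to better than 1%, rejects OU noise, periodic signals and
phase-randomized surrogates, and is affine-invariant.

## Operating point of the assembled network (known limitation)

Every printed parameter is honored, and the single-neuron and synaptic
levels are validated to a few percent. At the network level the literal
parameter reading places the model in an inhibition-dominated state: the
interneuron population responds with tuned rates (~5–30 Hz at high
contrast) while excitatory cells remain in a sparse sub-threshold regime
(≲0.2 Hz), sitting 2–3σ below threshold. The published conductance anchors
(≈20 nS excitatory / 40–50 nS inhibitory on an excitatory cell at full
contrast) indicate the original network recruited ~25–40% less inhibition
and kept excitatory cells at a few hertz. The reconstruction exposes one
dial for this — `lgn.inhibitory_attenuation` — and the value ≈0.78–0.80
restores tuned excitatory firing, but it sits within ~4% of a runaway
synchronized state at small sizes, so the shipped default keeps the
literal reading (1.0).

Consequences, reproduced and not: the contrast-controlled transition from
an asynchronous state (χ ~ N^{−1/2}) to a synchronous gamma-band
(~90–100 Hz) oscillation, its finite-size scaling, the interneuron-network
oscillation mechanism, the feed-forward/recurrent balance and the
PSP/connectivity tables are all reproduced quantitatively. The
*temporal-decorrelation contrast between coupled and uncoupled layers*
(fast-damping autocorrelograms and single-spike sensitivity only at Γ = 1)
is **not** reproduced at the default operating point: that phenomenon is
carried by the inter-layer excitatory loop, which is quiescent when
excitatory cells are silent; with layers coupled or not, the scaled-down
model damps its oscillation at an intermediate rate. The corresponding
acceptance checks are left failing rather than loosened.

## Problem sizes used by the test suite and acceptance script

PSP and connectivity checks are deterministic and run at reference
parameters. Stochastic regime checks run at total sizes 500–2500 with
10 s analysis windows after a 1 s warm-up (three wiring/noise seeds per
size for the χ–size fit); these sizes reproduce the asynchronous-scaling
slope and the synchrony transition while keeping a full run of the suite
and of `scripts/acceptance.py` in the minutes range. The full-size
(N = 10000, 100 s) coherence protocol ships as the preset
`fig8-mua-lfp-coherence`.
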