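# Unmodulated inter-layer excitation: the spatial modulation of the
# inter-layer excitatory profiles is removed (p1 = 0) at the same
# ring-average connection probability, spreading the same amount of
# inter-layer excitation across all angular distances.
n_exc: 4000
n_inh: 1000
neurons:
  E:
    kind: E
    tau_m: 23.3
    capacitance: 0.26
    e_leak: -57.8
    v_threshold: -45.2
    delta_t: 1.2
    v_reset: null
    v_cutoff: null
  I:
    kind: I
    tau_m: 11.65
    capacitance: 0.13
    e_leak: -57.8
    v_threshold: -45.2
    delta_t: 1.2
    v_reset: null
    v_cutoff: null
refractory:
  E:
    mode: soft
    components:
    - target: v_threshold
      amplitude: 22.9
      tau: 14.7
    - target: v_threshold
      amplitude: 13.5
      tau: 76.2
    - target: delta_t
      amplitude: 10.0
      tau: 17.7
    - target: inv_tau_m
      amplitude: 0.14
      tau: 14.3
    refractory_period: 2.0
  I:
    mode: hard
    components: []
    refractory_period: 2.0
synapse_classes:
  AMPA:E:
    name: AMPA
    target_kind: E
    tau_rise: 1.0
    tau_decay: 3.0
    peak_conductance: 1.0
    reversal: 0.0
    reference_psp: 0.84
  AMPA:I:
    name: AMPA
    target_kind: I
    tau_rise: 1.0
    tau_decay: 3.0
    peak_conductance: 1.5
    reversal: 0.0
    reference_psp: 2.07
  GABA:E:
    name: GABA
    target_kind: E
    tau_rise: 1.0
    tau_decay: 4.0
    peak_conductance: 4.0
    reversal: -75.0
    reference_psp: 1.13
  GABA:I:
    name: GABA
    target_kind: I
    tau_rise: 1.0
    tau_decay: 2.0
    peak_conductance: 4.0
    reversal: -75.0
    reference_psp: 1.36
  NMDA:E:
    name: NMDA
    target_kind: E
    tau_rise: 3.0
    tau_decay: 80.0
    peak_conductance: 0.14
    reversal: 0.0
    reference_psp: 0.5
  NMDA:I:
    name: NMDA
    target_kind: I
    tau_rise: 3.0
    tau_decay: 80.0
    peak_conductance: 0.0
    reversal: 0.0
    reference_psp: null
pathways:
- source_layer: upper
  source_kind: E
  target_layer: upper
  target_kind: E
  p0: 0.06
  p1: 0.06
  latency: 1.0
  interlayer: false
- source_layer: upper
  source_kind: I
  target_layer: upper
  target_kind: E
  p0: 0.24
  p1: 0.12
  latency: 1.0
  interlayer: false
- source_layer: upper
  source_kind: E
  target_layer: upper
  target_kind: I
  p0: 0.06
  p1: 0.06
  latency: 1.0
  interlayer: false
- source_layer: upper
  source_kind: I
  target_layer: upper
  target_kind: I
  p0: 0.24
  p1: 0.12
  latency: 1.0
  interlayer: false
- source_layer: lower
  source_kind: E
  target_layer: lower
  target_kind: E
  p0: 0.06
  p1: 0.06
  latency: 1.0
  interlayer: false
- source_layer: lower
  source_kind: I
  target_layer: lower
  target_kind: E
  p0: 0.24
  p1: 0.12
  latency: 1.0
  interlayer: false
- source_layer: lower
  source_kind: E
  target_layer: lower
  target_kind: I
  p0: 0.06
  p1: 0.06
  latency: 1.0
  interlayer: false
- source_layer: lower
  source_kind: I
  target_layer: lower
  target_kind: I
  p0: 0.24
  p1: 0.12
  latency: 1.0
  interlayer: false
- source_layer: upper
  source_kind: E
  target_layer: lower
  target_kind: E
  p0: 0.06
  p1: 0.0
  latency: 3.0
  interlayer: true
- source_layer: upper
  source_kind: E
  target_layer: lower
  target_kind: I
  p0: 0.06
  p1: 0.0
  latency: 3.0
  interlayer: true
- source_layer: lower
  source_kind: E
  target_layer: upper
  target_kind: E
  p0: 0.06
  p1: 0.0
  latency: 1.0
  interlayer: true
- source_layer: lower
  source_kind: E
  target_layer: upper
  target_kind: I
  p0: 0.07
  p1: 0.0
  latency: 1.0
  interlayer: true
- source_layer: upper
  source_kind: I
  target_layer: lower
  target_kind: E
  p0: 0.12
  p1: 0.0
  latency: 3.0
  interlayer: true
- source_layer: lower
  source_kind: I
  target_layer: upper
  target_kind: E
  p0: 0.12
  p1: 0.0
  latency: 1.0
  interlayer: true
- source_layer: upper
  source_kind: I
  target_layer: lower
  target_kind: I
  p0: 0.12
  p1: 0.0
  latency: 3.0
  interlayer: true
- source_layer: lower
  source_kind: I
  target_layer: upper
  target_kind: I
  p0: 0.12
  p1: 0.0
  latency: 1.0
  interlayer: true
lgn:
  g_lgn: 1.0
  rate_offset: 150.0
  rate_gain: 2850.0
  dark_rate: 5.0
  max_rate: 48.0
  tuning_broadness: 1.0
  lower_layer_attenuation: 0.5
  inhibitory_attenuation: 1.0
  contrast_log_scale: 100.0
background:
  g_bg: 10.0
  mean_rate: 10.0
  volatility: 1.0
  filter_time: 10.0
interlayer_scale: 1.0
gamma_scope: both
integration_step: 0.2
master_seed: 0
ref_n_exc: 4000
ref_n_inh: 1000
size_scaling: preserve
probability_overflow: error
schema_version: 1
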