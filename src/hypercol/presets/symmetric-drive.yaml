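# Increased-symmetry variant: the lower layer receives the same LGN rate
# as the upper layer and the upper-to-lower latency is shortened to match
# the lower-to-upper one.
lgn:
  lower_layer_attenuation: 1.0
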