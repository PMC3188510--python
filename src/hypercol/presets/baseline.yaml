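# Baseline hypercolumn: all table defaults (reference size 2x(4000+1000)).
# An empty document resolves to the built-in defaults.
{}
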