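# Large-variance noise variant (synthetic stand-in): fewer, stronger LGN
# afferents -- four-fold peak conductance at one quarter of the rate, so the
# mean feed-forward drive is unchanged while its variance quadruples.  The
# published variant's exact table is not reproduced here; this file realizes
# the same manipulation.
lgn:
  g_lgn: 4.0
  rate_offset: 37.5
  rate_gain: 712.5
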