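analyte,level_75,level_100,level_125,printed_mean,printed_rsd,printed_ci_low,printed_ci_high
CA,101.41,100.10,99.96,100.49,0.99,99.73,101.25
VX-1,99.77,99.55,100.21,99.84,0.57,99.40,100.28
VX-2,100.40,99.02,100.06,99.83,0.90,99.13,100.52
RU,100.09,100.40,100.22,100.24,0.21,100.08,100.40
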